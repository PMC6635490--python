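# Reference organ masses (g) of the ORNL/Cristy-Eckerman adult stylized
# phantom (ORNL/TM-8381 hermaphrodite adult), used for organ-dose mass
# correction so voxel dosimetry can be compared with organ-based dosimetry.
organ,reference_mass_g
gallbladder_wall,10.5
heart_wall,316.0
kidneys,299.0
liver,1910.0
lungs,999.0
pancreas,94.3
spleen,183.0
stomach_wall,158.0
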