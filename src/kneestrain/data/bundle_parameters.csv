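# Per-bundle constitutive parameters for the 1D ligament elements.
# Columns: name, k_N (linear-region stiffness, N per unit strain),
#          reference_strain (pre-strain at full extension, dimensionless),
#          eps_l (toe-to-linear transition strain, dimensionless).
# Stiffnesses and most reference strains follow the Blankevoort et al. (1991)
# 1D-element literature values; the ACL bundle pre-strains are set to the
# 6% (AM) / 10% (PL) extension values used by this model. The AM=6%, PL=10%
# pairing is an inference from the flexion behaviour of the two bundles
# (AM near-isometric, PL slack in flexion); swap here if needed.
name,k_N,reference_strain,eps_l
ACL_AM,5000,0.06,0.03
ACL_PL,5000,0.10,0.03
PCL_AL,9000,-0.24,0.03
PCL_PM,9000,-0.03,0.03
MCL_ANT,2750,0.04,0.03
MCL_CEN,2750,0.04,0.03
MCL_POS,2750,0.03,0.03
LCL_ANT,2000,-0.25,0.03
LCL_CEN,2000,-0.05,0.03
LCL_POS,2000,0.08,0.03
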