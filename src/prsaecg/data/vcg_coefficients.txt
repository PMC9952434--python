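# Wilson-tetrahedron -> orthogonal VCG transform coefficients, version 1.
#
# The unnormalized dipole projection is
#   (vpx, vpy, vpz)^T = (1/matrix_scale) * M * (VL-VR, VF-VR, VB-VR)^T
# and the direction cosines are (px,py,pz) = (vpx,vpy,vpz)/|vp|.
# The per-sample gain is
#   K = (1/k_scale) * sqrt(k_e2 * E^2 + k_vb2 * VB^2),
#   E^2 = (VL-VR)^2 + (1/e2_div) * (VF-VR + VF-VL)^2
# and the VCG components are (Vx,Vy,Vz) = 3 * K * (px,py,pz).
#
# Transcribed from the updated tetrahedron coefficient matrix of the
# published transform (the typeset source is ambiguous in plain-text form;
# this transcription is the parse in which each axis is dominated by its
# anatomically matching lead difference: X by VL-VR, Y by VF-VR, Z by
# VB-VR, and E^2 is the Einthoven frontal-plane magnitude, which is
# reference-invariant).  A corrected transcription is a data change here,
# not a code change.
matrix_scale = 22
m_xx =  27
m_xy = -20
m_xz = -26
m_yx =   5
m_yy =  55
m_yz =  15
m_zx = -30
m_zy = -52
m_zz = 139
k_scale = 33
k_e2 = 8
k_vb2 = 1
e2_div = 3
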