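"""Physical constants and unit conversions.

All internal computations use SI units (seconds, meters, tesla, radians).
User-facing quantities follow MRI conventions: times in ms, gradient
amplitudes in mT/m, velocities in mm/s, diffusivities in um^2/ms,
b-values in s/mm^2 and c-values in s/mm. Conversion happens once, at the
API boundary, to keep gamma^2 G^2 products free of unit mistakes.
"""

#: Gyromagnetic ratio of the proton, rad s^-1 T^-1.
GAMMA = 2.6752218744e8

# --- time ---
MS_TO_S = 1e-3
S_TO_MS = 1e3

# --- gradient amplitude ---
MT_PER_M_TO_T_PER_M = 1e-3
T_PER_M_TO_MT_PER_M = 1e3

# --- velocity ---
MM_PER_S_TO_M_PER_S = 1e-3
M_PER_S_TO_MM_PER_S = 1e3

# --- diffusivity (um^2/ms == 1e-9 m^2/s) ---
UM2_PER_MS_TO_M2_PER_S = 1e-9
M2_PER_S_TO_UM2_PER_MS = 1e9

# --- b-value (s/mm^2 == 1e6 s/m^2) ---
S_PER_MM2_TO_S_PER_M2 = 1e6
S_PER_M2_TO_S_PER_MM2 = 1e-6

# --- c-value (s/mm == 1e3 s/m) ---
S_PER_MM_TO_S_PER_M = 1e3
S_PER_M_TO_S_PER_MM = 1e-3

#: b [s/mm^2] times D [um^2/ms] must be scaled by this to be dimensionless.
B_TIMES_D = S_PER_MM2_TO_S_PER_M2 * UM2_PER_MS_TO_M2_PER_S  # = 1e-3
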