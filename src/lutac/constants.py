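"""Physical constants shared across the package.

All lengths are millimetres, times picoseconds (unless a suffix says
otherwise), energies keV and attenuation coefficients mm^-1.
"""

#: Speed of light in mm per picosecond.
C_MM_PER_PS = 0.299792

#: Ratio of linear attenuation coefficients at 307 keV and 511 keV,
#: obtained by a linear fit across human tissues; used to map the
#: 511 keV mu-map onto the 307 keV transmission energy.
ETA_307 = 1.2276

#: Linear attenuation coefficient of water at 511 keV (mm^-1).
MU_WATER_511 = 0.0096

#: Linear attenuation coefficient of LYSO at 511 keV (mm^-1).
MU_LYSO_511 = 0.0815

#: Half-life of F-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: Principal prompt-gamma lines of Lu-176 decay and their emission
#: probabilities per beta decay.
LU176_GAMMA_LINES = {307.0: 1.00, 202.0: 0.833, 88.0: 0.155}

#: Conversion between a Gaussian FWHM and its standard deviation.
FWHM_TO_SIGMA = 1.0 / 2.354820045030949
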