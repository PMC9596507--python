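"""Physical constants used throughout the toolkit.

All field maps are carried in Hz. Geometry is expressed in scanner-frame
millimetres with the origin at magnet isocenter and z along B0 (positive z
toward the head); "caudal" offsets are therefore negative z.
"""

import numpy as np

#: Proton gyromagnetic ratio over 2*pi, Hz per tesla.
GAMMA_HZ_PER_T = 42.577e6

#: Vacuum permeability, T*m/A.
MU0 = 4e-7 * np.pi

#: Resistivity of copper at room temperature, ohm*m.
COPPER_RESISTIVITY = 1.68e-8
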