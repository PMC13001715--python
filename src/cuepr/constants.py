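"""Physical constants (CODATA 2018) and unit helpers.

All spectroscopic conversions in the package go through this module so that
g-value/field/frequency arithmetic is consistent everywhere.
"""

PLANCK_H = 6.62607015e-34  # J s
BOHR_MAGNETON = 9.2740100783e-24  # J / T

#: Dipolar frequency scale for a g = 2 electron-spin pair: nu_dd = D_NM3 / r^3
#: with r in nm and nu_dd in MHz.
DIPOLAR_MHZ_NM3 = 52.04

GAUSS_PER_TESLA = 1e4
NM_PER_ANGSTROM = 0.1


def field_for_g(g: float, mw_freq_ghz: float) -> float:
    """Resonance field in Gauss for an electron with g-value ``g`` at
    microwave frequency ``mw_freq_ghz`` (GHz): B = h nu / (g muB)."""
    b_tesla = PLANCK_H * mw_freq_ghz * 1e9 / (g * BOHR_MAGNETON)
    return b_tesla * GAUSS_PER_TESLA


def mhz_to_gauss(a_mhz: float, g: float) -> float:
    """Convert a hyperfine coupling in MHz to field units (Gauss) for an
    electron of g-value ``g``: a[B] = A h / (g muB)."""
    a_tesla = a_mhz * 1e6 * PLANCK_H / (g * BOHR_MAGNETON)
    return a_tesla * GAUSS_PER_TESLA
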