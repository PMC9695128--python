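"""Independent high-precision Lorenz-Mie reference for cross-checking.

Evaluates the Mie coefficients directly from arbitrary-precision
half-integer Bessel functions (mpmath), with no recurrences shared with
the production implementation.  Used only as a test oracle.
"""

import mpmath as mp

mp.mp.dps = 30


def _psi(n, z):
    return mp.sqrt(mp.pi * z / 2) * mp.besselj(n + mp.mpf(1) / 2, z)


def _chi(n, z):
    return -mp.sqrt(mp.pi * z / 2) * mp.bessely(n + mp.mpf(1) / 2, z)


def _dpsi(n, z):
    return _psi(n - 1, z) - n / z * _psi(n, z)


def _dchi(n, z):
    return _chi(n - 1, z) - n / z * _chi(n, z)


def mie_reference(m: complex, x: float) -> tuple[float, float, float]:
    """(Q_ext, Q_sca, g) from direct Bessel evaluation at 30 digits."""
    m = mp.mpc(m)
    x = mp.mpf(x)
    nmax = int(mp.ceil(x + 4 * x ** (mp.mpf(1) / 3) + 2))
    mx = m * x
    ab = []
    qe = qs = mp.mpf(0)
    for n in range(1, nmax + 1):
        pn_x, pn_mx = _psi(n, x), _psi(n, mx)
        dpn_x, dpn_mx = _dpsi(n, x), _dpsi(n, mx)
        xn = pn_x - 1j * _chi(n, x)
        dxn = dpn_x - 1j * _dchi(n, x)
        a = (m * pn_mx * dpn_x - pn_x * dpn_mx) / (m * pn_mx * dxn - xn * dpn_mx)
        b = (pn_mx * dpn_x - m * pn_x * dpn_mx) / (pn_mx * dxn - m * xn * dpn_mx)
        ab.append((a, b))
        qe += (2 * n + 1) * (a.real + b.real)
        qs += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
    gsum = mp.mpf(0)
    for n in range(1, nmax):
        a, b = ab[n - 1]
        a1, b1 = ab[n]
        gsum += n * (n + 2) / mp.mpf(n + 1) * (
            (a * mp.conj(a1)).real + (b * mp.conj(b1)).real)
    for n in range(1, nmax + 1):
        a, b = ab[n - 1]
        gsum += (2 * n + 1) / mp.mpf(n * (n + 1)) * (a * mp.conj(b)).real
    qe *= 2 / x**2
    qs *= 2 / x**2
    return float(qe), float(qs), float(4 / x**2 / qs * gsum)
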