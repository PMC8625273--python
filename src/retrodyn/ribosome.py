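"""Quasi-steady-state ribosome-competition kinetics.

The saturating R_L production law of the ribosome variant is derived from a
kinetic scheme in which L1 mRNA (``mL``) and the pooled mRNA of all other
genes (``mq``) bind reversibly to free ribosomes ``E`` and are translated
from the bound complexes.  Treating the complex concentrations as at quasi
steady state and eliminating them yields

    mLE* = E_tot * mL / (c1 * Kd + mL),    c1 = 1 + mq / Khat_d,

with dissociation constants ``Kd ~ k_minus1/k1`` and ``Khat_d ~
khat_minus1/khat1`` (valid when translation is much slower than unbinding).
With a linear mRNA-per-copy relation ``mL = c2 * L`` this collapses into the
Michaelis-Menten law ``v_R = v_max * L / (k_r + L)`` with ``v_max = k2 *
E_tot`` and ``k_r = c1 * c2 * Kd``.

This module exposes the closed form and a brute-force mode that integrates
the two complex ODEs to steady state, as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


@dataclass(frozen=True)
class RibosomeKinetics:
    """Rate constants of the mRNA-ribosome binding scheme.

    ``k1, k_minus1, k2`` govern the L1-mRNA/ribosome complex (binding,
    unbinding, translation); the hatted constants govern the complex with
    the pooled non-transposon mRNA.  ``E_tot`` is the total ribosome amount,
    ``mL`` and ``mq`` the free mRNA amounts.
    """

    k1: float
    k_minus1: float
    k2: float
    khat1: float
    khat_minus1: float
    khat2: float
    E_tot: float
    mL: float
    mq: float

    def __post_init__(self) -> None:
        for name in (
            "k1",
            "k_minus1",
            "k2",
            "khat1",
            "khat_minus1",
            "khat2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.E_tot < 0 or self.mL < 0 or self.mq < 0:
            raise ValueError("E_tot, mL and mq must be non-negative")

    @property
    def Kd(self) -> float:
        """Dissociation constant of the mL.E complex, (k2 + k_minus1)/k1."""
        return (self.k2 + self.k_minus1) / self.k1

    @property
    def Khat_d(self) -> float:
        return (self.khat2 + self.khat_minus1) / self.khat1

    @property
    def c1(self) -> float:
        """Competition factor 1 + mq/Khat_d contributed by the other mRNAs."""
        return 1.0 + self.mq / self.Khat_d


def qss_complex_occupancy(
    kin: RibosomeKinetics, *, brute_force: bool = False
) -> float:
    """Stationary amount of the translating mL.E complex.

    Closed form: ``E_tot * mL / (c1*Kd + mL)``.  With ``brute_force=True``
    the two complex ODEs

        d(mLE)/dt = k1*mL*E - (k_minus1 + k2)*mLE
        d(mqE)/dt = khat1*mq*E - (khat_minus1 + khat2)*mqE

    with ``E = E_tot - mLE - mqE`` are integrated to steady state instead;
    the two routes agree when translation is slow (``k2 << k_minus1``).
    """
    denom = kin.c1 * kin.Kd + kin.mL
    if denom == 0:
        raise ZeroDivisionError("c1*Kd + mL is zero")
    if not brute_force:
        return kin.E_tot * kin.mL / denom

    def rhs(_t, y):
        mLE, mqE = y
        E = kin.E_tot - mLE - mqE
        return [
            kin.k1 * kin.mL * E - (kin.k_minus1 + kin.k2) * mLE,
            kin.khat1 * kin.mq * E - (kin.khat_minus1 + kin.khat2) * mqE,
        ]

    # Relaxation time ~ 1/min(rate); integrate well past it.
    rates = [kin.k_minus1 + kin.k2, kin.khat_minus1 + kin.khat2, kin.k1, kin.khat1]
    t_end = 200.0 / min(rates)
    sol = solve_ivp(
        rhs, (0.0, t_end), [0.0, 0.0], method="LSODA", rtol=1e-10, atol=1e-12
    )
    if not sol.success:
        raise RuntimeError(f"QSS brute-force integration failed: {sol.message}")
    drift = np.abs(rhs(sol.t[-1], sol.y[:, -1])).max()
    if drift > 1e-8 * max(1.0, kin.E_tot):
        raise RuntimeError("QSS brute-force integration did not reach steady state")
    return float(sol.y[0, -1])
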