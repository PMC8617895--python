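"""Polymer elasticity of the stretched polypeptide and the folded core.

The unfolded chain is described by the inextensible worm-like chain (WLC)
through the standard interpolation formula between the low- and high-force
regimes,

    f(z) = (kBT / 4 Lp) [ (1 - z)^(-2) + 4 z - 1 ],    z = X / L,

with ``Lp`` the persistence length and ``L = n_mon * d_mon`` the contour
length. The folded protein under tension is modelled as a single orientable
dipole — one Kuhn segment of the freely-jointed chain (FJC) — whose mean
extension follows the Langevin function.

The formula is monotone in z on (0, 1); its inverse (extension at a given
force) is computed by bisection, which converges unconditionally on that
branch. All functions broadcast over numpy arrays of force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thermal import ThermalContext

__all__ = [
    "ElasticParams",
    "wlc_force",
    "relative_extension",
    "wlc_extension",
    "monomers_from_extension",
    "fjc_dipole_extension",
    "released_extension",
]

_Z_MAX = 1.0 - 1e-12
_BISECT_TOL = 1e-12
_BISECT_MAX_ITER = 200


@dataclass(frozen=True)
class ElasticParams:
    """Elastic description of one molecule.

    Parameters
    ----------
    persistence_length : float
        WLC persistence length Lp of the unfolded chain, nm.
    monomer_length : float
        Contour length per monomer (amino acid or nucleotide), nm.
    n_monomers : float
        Number of monomers released upon unfolding.
    dipole_length : float
        Length of the folded-core dipole (N-to-C termini distance), nm.
    """

    persistence_length: float
    monomer_length: float
    n_monomers: float
    dipole_length: float

    def __post_init__(self) -> None:
        for name in ("persistence_length", "monomer_length", "dipole_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_monomers < 0:
            raise ValueError(f"n_monomers must be >= 0, got {self.n_monomers}")

    @property
    def contour_length(self) -> float:
        """Contour length L = n_monomers * monomer_length, nm."""
        return self.n_monomers * self.monomer_length

    @classmethod
    def barnase(cls) -> "ElasticParams":
        """Elastic parameters of the 110-residue protein barnase:
        Lp = 0.8 nm, 0.37 nm per amino acid, 3 nm folded-core dipole."""
        return cls(
            persistence_length=0.8,
            monomer_length=0.37,
            n_monomers=110,
            dipole_length=3.0,
        )


def wlc_force(z, persistence_length: float, ctx: ThermalContext):
    """Force (pN) of the WLC interpolation formula at relative extension z."""
    z = np.asarray(z, dtype=float)
    return ctx.kBT / (4.0 * persistence_length) * ((1.0 - z) ** -2 + 4.0 * z - 1.0)


def relative_extension(f, persistence_length: float, ctx: ThermalContext):
    """Invert the WLC interpolation formula: relative extension z in (0, 1).

    Bisection on z in [0, 1 - 1e-12] to absolute tolerance 1e-12. The
    algebraic rearrangement of the formula is a cubic with spurious roots
    outside (0, 1); bisection on the monotone physical branch avoids them.

    Raises
    ------
    ValueError
        If any force is non-positive.
    RuntimeError
        If bisection fails to bracket or converge.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("relative_extension requires force > 0")
    lo = np.zeros_like(f_arr)
    hi = np.full_like(f_arr, _Z_MAX)
    if np.any(wlc_force(hi, persistence_length, ctx) < f_arr):
        raise RuntimeError("force exceeds the invertible WLC range")
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        high_side = wlc_force(mid, persistence_length, ctx) >= f_arr
        hi = np.where(high_side, mid, hi)
        lo = np.where(high_side, lo, mid)
        if np.max(hi - lo) < _BISECT_TOL:
            break
    else:
        raise RuntimeError("WLC inversion did not converge")
    z = 0.5 * (lo + hi)
    return z if f_arr.ndim else float(z)


def wlc_extension(f, params: ElasticParams, ctx: ThermalContext):
    """Extension X(f) = z(f) * L of the released chain, nm."""
    z = relative_extension(f, params.persistence_length, ctx)
    return z * params.contour_length


def monomers_from_extension(
    f,
    x,
    persistence_length: float,
    monomer_length: float,
    ctx: ThermalContext,
    dipole_length: float | None = None,
):
    """Convert a distance along the extension coordinate into monomer units.

    n = x / (z(f) * monomer_length), the number of monomers whose stretched
    extension at force ``f`` equals ``x``. Real-valued by design; rounding, if
    any, belongs at the reporting stage.

    If ``dipole_length`` is given, the FJC dipole extension of the folded core
    at ``f`` is added to ``x`` before converting. This alternative convention
    treats the measured barrier distance as excluding the folded-core
    contribution; it is off by default.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("monomers_from_extension requires x >= 0")
    if dipole_length is not None:
        x_arr = x_arr + fjc_dipole_extension(f, dipole_length, ctx)
    z = relative_extension(f, persistence_length, ctx)
    n = x_arr / (z * monomer_length)
    return n if np.asarray(x).ndim or np.asarray(f).ndim else float(n)


def fjc_dipole_extension(f, dipole_length: float, ctx: ThermalContext):
    """Mean extension of a single orientable segment of length d0 at force f.

    x_d(f) = d0 * [coth(b) - 1/b] with b = beta * f * d0 (the Langevin
    function). Below b < 1e-4 the series b/3 - b^3/45 is used to avoid
    catastrophic cancellation; x_d(0) = 0 exactly.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("fjc_dipole_extension requires force >= 0")
    b = ctx.beta * f_arr * dipole_length
    small = b < 1e-4
    b_safe = np.where(small, 1.0, b)
    langevin = np.where(
        small,
        b / 3.0 - b**3 / 45.0,
        1.0 / np.tanh(b_safe) - 1.0 / b_safe,
    )
    x_d = dipole_length * langevin
    return x_d if f_arr.ndim else float(x_d)


def released_extension(f, params: ElasticParams, ctx: ThermalContext):
    """Theoretical extension released upon unfolding at force f, nm.

    x_m,th(f) = X(f) - x_d(f): the WLC extension of the full chain minus the
    pre-rupture extension of the folded core modelled as an FJC dipole.
    """
    return wlc_extension(f, params, ctx) - fjc_dipole_extension(
        f, params.dipole_length, ctx
    )
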