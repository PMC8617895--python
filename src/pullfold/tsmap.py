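"""Force-dependent transition-state (TS) position in amino-acid units.

The straight-line Bell-Evans fits give a roughly constant barrier-to-native
distance x_dagger. Holding x_dagger fixed and converting it to monomers with
the WLC at each force yields a number of unzipped residues at the barrier,

    naa_dagger(f) = x_dagger / (z(f) * d_mon),

that *decreases* with force — the Leffler-Hammond shift of the barrier
toward the native state. The complementary count naa_star(f) = N -
naa_dagger(f) then maps back to a strongly force-dependent barrier-to-U
distance x_star(f) = naa_star(f) * d_mon * z(f), and the mechanical
fragility mu(f) = (x_dagger - x_star) / (x_dagger + x_star) interpolates
from compliant (mu > 0) to brittle (mu < 0) response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elastic import ElasticParams, monomers_from_extension, relative_extension
from .thermal import ThermalContext

__all__ = ["TSProfile", "ts_profile", "fragility_profile", "total_monomers"]


@dataclass
class TSProfile:
    """Force grids of the TS position under the constant-x_dagger convention."""

    force: np.ndarray  # pN
    naa_dagger: np.ndarray  # residues unzipped at the barrier, from N
    naa_star: np.ndarray  # residues absorbed at the barrier, from U
    x_star: np.ndarray  # nm
    x1aa: np.ndarray  # extension per residue z(f)*d_mon, nm
    mu: np.ndarray  # fragility, dimensionless
    x_dagger_const: float  # nm
    n_monomers: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "force_pN": self.force,
                "naa_dagger": self.naa_dagger,
                "naa_star": self.naa_star,
                "x_star_nm": self.x_star,
                "x1aa_nm": self.x1aa,
                "mu": self.mu,
            }
        )


def ts_profile(
    f_grid,
    x_dagger: float,
    elastic: ElasticParams,
    ctx: ThermalContext,
) -> TSProfile:
    """TS profile on a sorted positive force grid, holding x_dagger constant.

    Grid points where the implied naa_dagger would exceed the total monomer
    count (possible at very low force, where each residue stretches very
    little) are truncated away with a warning; if no point survives, a
    ValueError naming the offending force is raised.
    """
    f = np.asarray(f_grid, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("f_grid must be a non-empty 1-D array")
    if np.any(f <= 0) or np.any(np.diff(f) <= 0):
        raise ValueError("f_grid must be positive and strictly increasing")
    if not x_dagger > 0:
        raise ValueError("x_dagger must be > 0")

    z = relative_extension(f, elastic.persistence_length, ctx)
    x1aa = z * elastic.monomer_length
    naa_dagger = x_dagger / x1aa
    valid = naa_dagger <= elastic.n_monomers
    if not np.any(valid):
        raise ValueError(
            f"naa_dagger exceeds the {elastic.n_monomers:g}-monomer chain at every "
            f"grid force (first offending force {f[0]:g} pN)"
        )
    if not np.all(valid):
        warnings.warn(
            f"truncated {int(np.sum(~valid))} low-force grid point(s) where "
            f"naa_dagger would exceed {elastic.n_monomers:g} monomers "
            f"(up to {f[~valid].max():g} pN)",
            UserWarning,
            stacklevel=2,
        )
        f, z, x1aa, naa_dagger = f[valid], z[valid], x1aa[valid], naa_dagger[valid]
    naa_star = elastic.n_monomers - naa_dagger
    x_star = naa_star * x1aa
    mu = (x_dagger - x_star) / (x_dagger + x_star)
    return TSProfile(
        force=f,
        naa_dagger=naa_dagger,
        naa_star=naa_star,
        x_star=x_star,
        x1aa=x1aa,
        mu=mu,
        x_dagger_const=float(x_dagger),
        n_monomers=float(elastic.n_monomers),
    )


def fragility_profile(ts: TSProfile) -> pd.DataFrame:
    """Fragility mu(f) as a two-column table (force_pN, mu)."""
    return pd.DataFrame({"force_pN": ts.force, "mu": ts.mu})


def total_monomers(
    f: float,
    x_dagger: float,
    x_star: float,
    elastic: ElasticParams,
    ctx: ThermalContext,
    include_dipole: bool = False,
) -> float:
    """Total residues implied by both barrier distances at one force.

    naa_tot = naa(x_dagger; f) + naa(x_star; f). With ``include_dipole`` the
    folded-core dipole extension is added to x_dagger before conversion (an
    alternative convention for the native-side distance).
    """
    d0 = elastic.dipole_length if include_dipole else None
    n_dagger = monomers_from_extension(
        f, x_dagger, elastic.persistence_length, elastic.monomer_length, ctx, dipole_length=d0
    )
    n_star = monomers_from_extension(
        f, x_star, elastic.persistence_length, elastic.monomer_length, ctx
    )
    return float(n_dagger + n_star)
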