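"""Community trait metrics for species assemblages.

Implements the four single-trait community metrics used throughout the
pipeline: the community-weighted mean (CWM), functional divergence as Rao's
quadratic entropy on a Gower dissimilarity matrix, functional richness
(FRic) as the occupied fraction of the pool trait range, and functional
evenness (FEve) as the minimum-spanning-tree evenness index (in one trait
dimension the MST is the trait-ordered chain).

All metrics weight species by relative abundance of individual counts and
normalise trait differences over the *whole species pool*, so values are
comparable across assemblages drawn from the same pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "SpeciesPool",
    "DissimilarityMatrix",
    "relative_abundances",
    "gower_dissimilarity",
    "cwm",
    "rao_fdiv",
    "fric",
    "feve",
    "metrics_table",
]


@dataclass(frozen=True)
class Species:
    """One species' trait record.

    Parameters
    ----------
    species_id
        Unique short label (e.g. ``"Ps"`` for *Porcellio scaber*).
    fresh_body_mass
        Mean fresh body mass at the start of the experiment, mg.
    consumption_rate
        Mean leaf-litter consumption rate, mg individual^-1 day^-1.
    consumption_sd
        Standard deviation of the consumption rate, same units.
    """

    species_id: str
    fresh_body_mass: float
    consumption_rate: float
    consumption_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fresh_body_mass <= 0:
            raise ValueError(
                f"species {self.species_id!r}: fresh_body_mass must be > 0, "
                f"got {self.fresh_body_mass}"
            )
        if self.consumption_rate < 0:
            raise ValueError(
                f"species {self.species_id!r}: consumption_rate must be >= 0"
            )
        if self.consumption_sd < 0:
            raise ValueError(
                f"species {self.species_id!r}: consumption_sd must be >= 0"
            )


class SpeciesPool:
    """An ordered collection of species with numeric traits.

    The pool anchors every downstream computation: Gower normalisation
    ranges, CWM trait values, and body masses for biomass budgeting.
    """

    _TRAITS = ("fresh_body_mass", "consumption_rate", "consumption_sd")

    def __init__(self, species: Sequence[Species]):
        ids = [sp.species_id for sp in species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")
        self._species = tuple(species)
        self._index = {sp.species_id: k for k, sp in enumerate(self._species)}

    def __len__(self) -> int:
        return len(self._species)

    def __iter__(self):
        return iter(self._species)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    def __getitem__(self, species_id: str) -> Species:
        return self._species[self._index[species_id]]

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesPool) and self._species == other._species

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sp.species_id for sp in self._species)

    def trait(self, name: str) -> np.ndarray:
        """Trait values in pool order."""
        if name not in self._TRAITS:
            raise KeyError(f"unknown trait {name!r}; available: {self._TRAITS}")
        return np.array([getattr(sp, name) for sp in self._species], dtype=float)

    def trait_range(self, name: str) -> float:
        x = self.trait(name)
        return float(x.max() - x.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.ids,
                "fresh_body_mass_mg": self.trait("fresh_body_mass"),
                "consumption_rate_mg_ind_day": self.trait("consumption_rate"),
                "consumption_sd": self.trait("consumption_sd"),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeciesPool":
        required = {
            "species_id",
            "fresh_body_mass_mg",
            "consumption_rate_mg_ind_day",
            "consumption_sd",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        species = [
            Species(
                species_id=str(row.species_id),
                fresh_body_mass=float(row.fresh_body_mass_mg),
                consumption_rate=float(row.consumption_rate_mg_ind_day),
                consumption_sd=float(row.consumption_sd),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(species)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric species-by-species dissimilarity with entries in [0, 1]."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("self-dissimilarity must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def get(self, i: str, j: str) -> float:
        ix = {s: k for k, s in enumerate(self.ids)}
        return float(self.values[ix[i], ix[j]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        ix = {s: k for k, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in ix]
        if missing:
            raise KeyError(f"species missing from dissimilarity matrix: {missing}")
        sel = [ix[s] for s in ids]
        return self.values[np.ix_(sel, sel)]


def _present(counts: Mapping[str, float]) -> list[str]:
    """Species ids with positive abundance; validates the abundance vector.

    Abundances are individual counts at design time but may be fractional
    effective abundances after mortality correction.
    """
    if not counts:
        raise ValueError("empty abundance vector")
    present = []
    for sp, n in counts.items():
        if not np.isfinite(n) or n < 0:
            raise ValueError(f"abundance for {sp!r} must be finite and >= 0, got {n}")
        if n > 0:
            present.append(sp)
    if not present:
        raise ValueError("abundance vector has no positive counts")
    return present


def relative_abundances(counts: Mapping[str, float]) -> dict[str, float]:
    """Relative abundances p_i = n_i / sum(n) over species with n_i > 0."""
    present = _present(counts)
    total = float(sum(counts[sp] for sp in present))
    return {sp: counts[sp] / total for sp in present}


def gower_dissimilarity(
    pool: SpeciesPool, trait_names: Sequence[str] | str
) -> DissimilarityMatrix:
    """Range-normalised (Gower) trait dissimilarity over the whole pool.

    For one trait, ``d_ij = |x_i - x_j| / (max x - min x)`` with the range
    taken over the entire pool; for several traits the unweighted mean of
    the per-trait normalised differences.
    """
    if isinstance(trait_names, str):
        trait_names = [trait_names]
    if len(pool) < 2:
        raise ValueError("Gower dissimilarity needs at least 2 species")
    layers = []
    for name in trait_names:
        x = pool.trait(name)
        rng = x.max() - x.min()
        if rng <= 0:
            raise ValueError(f"trait {name!r} has zero range across the pool")
        layers.append(np.abs(x[:, None] - x[None, :]) / rng)
    d = np.mean(layers, axis=0)
    return DissimilarityMatrix(ids=pool.ids, values=d)


def cwm(counts: Mapping[str, int], pool: SpeciesPool, trait: str) -> float:
    """Community-weighted mean trait value, CWM = sum_i p_i x_i."""
    p = relative_abundances(counts)
    unknown = [sp for sp in p if sp not in pool]
    if unknown:
        raise KeyError(f"species not in pool: {unknown}")
    x = {sp.species_id: getattr(sp, trait) for sp in pool}
    return float(sum(p[sp] * x[sp] for sp in p))


def rao_fdiv(counts: Mapping[str, int], dissim: DissimilarityMatrix) -> float:
    """Rao's quadratic entropy Q = sum_ij p_i p_j d_ij.

    The expected trait dissimilarity between two individuals drawn at
    random (with replacement) from the assemblage; 0 for monocultures.
    """
    p = relative_abundances(counts)
    ids = list(p)
    d = dissim.submatrix(ids)
    pv = np.array([p[s] for s in ids])
    return float(pv @ d @ pv)


def fric(counts: Mapping[str, int], pool: SpeciesPool, trait: str) -> float:
    """Single-trait functional richness: occupied fraction of the pool range."""
    present = _present(counts)
    unknown = [sp for sp in present if sp not in pool]
    if unknown:
        raise KeyError(f"species not in pool: {unknown}")
    rng = pool.trait_range(trait)
    if rng <= 0:
        raise ValueError(f"trait {trait!r} has zero range across the pool")
    x = np.array([getattr(pool[sp], trait) for sp in present])
    return float((x.max() - x.min()) / rng)


def feve(counts: Mapping[str, int], pool: SpeciesPool, trait: str) -> float:
    """Functional evenness along one trait axis (MST chain form).

    Regularity of abundance spacing along the trait axis: species are
    ordered by trait value, each adjacent pair l gets a weighted evenness
    ``EW_l = d(i, j) / (p_i + p_j)``, partial evennesses ``PEW_l`` are the
    normalised EW, and

        FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)).

    Defined only for S >= 3 species present; returns NaN (with a log
    notice) below that.
    """
    p = relative_abundances(counts)
    unknown = [sp for sp in p if sp not in pool]
    if unknown:
        raise KeyError(f"species not in pool: {unknown}")
    if len(p) < 3:
        logger.info(
            "FEve undefined for %d species present (needs >= 3); returning NaN",
            len(p),
        )
        return float("nan")
    order = sorted(p, key=lambda sp: getattr(pool[sp], trait))
    x = np.array([getattr(pool[sp], trait) for sp in order])
    pv = np.array([p[sp] for sp in order])
    ew = np.abs(np.diff(x)) / (pv[:-1] + pv[1:])
    total = ew.sum()
    s = len(order)
    if total == 0:  # all present trait values identical
        return float("nan")
    pew = ew / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def metrics_table(
    assemblages: Mapping[str, Mapping[str, int]] | Iterable[tuple[str, Mapping[str, int]]],
    pool: SpeciesPool,
    trait: str = "consumption_rate",
) -> pd.DataFrame:
    """Compute all community metrics for a set of assemblages.

    Returns one row per assemblage with columns
    ``assemblage_id, biomass_g, cwm, fdiv_rao, fric, feve, richness``.
    """
    from .design import assemblage_biomass  # avoids a module cycle

    dissim = gower_dissimilarity(pool, trait)
    items = assemblages.items() if isinstance(assemblages, Mapping) else assemblages
    rows = []
    for aid, counts in items:
        present = _present(counts)
        rows.append(
            {
                "assemblage_id": aid,
                "biomass_g": assemblage_biomass(counts, pool),
                "cwm": cwm(counts, pool, trait),
                "fdiv_rao": rao_fdiv(counts, dissim),
                "fric": fric(counts, pool, trait),
                "feve": feve(counts, pool, trait),
                "richness": len(present),
            }
        )
    return pd.DataFrame(rows)
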