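"""Orthogonal CWM-FD assemblage design.

Community-weighted mean (CWM) and functional diversity (FD) are
mathematically interdependent: assemblages with extreme CWM can only have
low FD, so observational gradients confound the two. This module breaks
that dependence the way a manipulative experiment does: simulate a large
cloud of candidate assemblages under a total-biomass window, classify the
cloud's corners in the CWM-FD plane (high/high, high/low, low/high,
low/low), and select compositionally distinct assemblages from each corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .functional_metrics import SpeciesPool, gower_dissimilarity

__all__ = [
    "DesignConfig",
    "CandidateCloud",
    "Design",
    "assemblage_biomass",
    "simulate_candidates",
    "classify_corners",
    "select_design",
    "run_design",
]

CORNERS = ("HH", "HL", "LH", "LL")


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of the candidate simulation and corner selection.

    Defaults reproduce the published design regime: candidate assemblages
    of 2-4 species, at most 10 individuals per species, accepted only if
    total fresh biomass falls in [0.45, 0.65] g, with four assemblages
    selected per CWM-FD corner.
    """

    biomass_min: float = 0.45  # g
    biomass_max: float = 0.65  # g
    n_candidates: int = 5000
    richness_min: int = 2
    richness_max: int = 4
    max_count_per_species: int = 10
    corners: tuple[str, ...] = CORNERS
    assemblages_per_corner: int = 4
    corner_quantile: float = 0.25
    min_composition_distance: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.biomass_min < self.biomass_max:
            raise ValueError("require 0 < biomass_min < biomass_max")
        if not 0 < self.corner_quantile < 0.5:
            raise ValueError("corner_quantile must lie in (0, 0.5)")
        if self.assemblages_per_corner < 1:
            raise ValueError("assemblages_per_corner must be >= 1")
        if not 1 <= self.richness_min <= self.richness_max:
            raise ValueError("require 1 <= richness_min <= richness_max")


@dataclass
class CandidateCloud:
    """Simulated assemblages with attached biomass and functional metrics.

    ``table`` holds one row per candidate: count columns ``n_<species_id>``
    plus ``biomass_g``, ``cwm``, ``fdiv_rao``, ``richness`` and (after
    corner classification) ``corner``.
    """

    table: pd.DataFrame
    species_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.table)

    def counts_matrix(self) -> np.ndarray:
        return self.table[[f"n_{s}" for s in self.species_ids]].to_numpy(dtype=int)

    def counts_of(self, row: int) -> dict[str, int]:
        r = self.table.iloc[row]
        return {s: int(r[f"n_{s}"]) for s in self.species_ids if r[f"n_{s}"] > 0}


@dataclass
class Design:
    """A selected orthogonal design plus its provenance."""

    selected: pd.DataFrame  # assemblage_id, corner, n_<sp>..., biomass_g, cwm, fdiv_rao, richness
    config: DesignConfig
    species_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def counts_of(self, assemblage_id: str) -> dict[str, int]:
        row = self.selected.set_index("assemblage_id").loc[assemblage_id]
        return {s: int(row[f"n_{s}"]) for s in self.species_ids if row[f"n_{s}"] > 0}

    @property
    def assemblage_ids(self) -> list[str]:
        return list(self.selected["assemblage_id"])

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "species_ids": list(self.species_ids),
            "provenance": self.provenance,
            "selected": self.selected.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Design":
        payload = json.loads(text)
        cfg = payload["config"]
        cfg["corners"] = tuple(cfg["corners"])
        return cls(
            selected=pd.DataFrame(payload["selected"]),
            config=DesignConfig(**cfg),
            species_ids=tuple(payload["species_ids"]),
            provenance=payload.get("provenance", {}),
        )


def assemblage_biomass(counts: Mapping[str, int], pool: SpeciesPool) -> float:
    """Total fresh biomass of an assemblage in grams, reported to 3 decimals.

    Sums count x mean body mass (mg) and converts to g. Rounding is
    half-up on the decimal representation so printed table values such as
    435.5 mg -> 0.436 g are reproduced exactly.
    """
    total_mg = 0.0
    for sp, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for species {sp!r}")
        total_mg += n * pool[sp].fresh_body_mass
    # kill float fuzz before decimal rounding (masses carry 2 decimals)
    grams = Decimal(repr(round(total_mg, 6))) / Decimal(1000)
    return float(grams.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _raw_biomass_g(counts_matrix: np.ndarray, masses_mg: np.ndarray) -> np.ndarray:
    return counts_matrix @ masses_mg / 1000.0


def simulate_candidates(
    pool: SpeciesPool, config: DesignConfig, trait: str = "consumption_rate"
) -> CandidateCloud:
    """Rejection-sample >= n_candidates assemblages inside the biomass window.

    Each draw picks a species subset with richness uniform on
    [richness_min, richness_max], integer counts uniform on
    [1, max_count_per_species], and keeps the assemblage iff its total
    biomass lies within the window. Duplicate compositions are permitted
    in the cloud; uniqueness is only enforced at selection time.
    """
    s = len(pool)
    if s < config.richness_min:
        raise ValueError(
            f"pool has {s} species but richness_min={config.richness_min}: "
            "richness range infeasible"
        )
    rmax = min(config.richness_max, s)
    rng = np.random.default_rng(config.seed)
    masses = pool.trait("fresh_body_mass")
    rates = pool.trait(trait)
    dmat = gower_dissimilarity(pool, trait).values

    accepted: list[np.ndarray] = []
    n_acc = 0
    n_drawn = 0
    batch = max(4 * config.n_candidates, 1000)
    max_draws = 1000 * config.n_candidates
    while n_acc < config.n_candidates:
        if n_drawn >= max_draws:
            raise RuntimeError(
                f"biomass window [{config.biomass_min}, {config.biomass_max}] g "
                f"accepted only {n_acc}/{config.n_candidates} candidates after "
                f"{n_drawn} draws; constraints may be unsatisfiable"
            )
        richness = rng.integers(config.richness_min, rmax + 1, size=batch)
        counts = rng.integers(1, config.max_count_per_species + 1, size=(batch, s))
        # zero out species beyond each draw's richness via a random subset mask
        order = np.argsort(rng.random((batch, s)), axis=1)
        mask = order < richness[:, None]
        counts = counts * mask
        biomass = _raw_biomass_g(counts, masses)
        keep = (biomass >= config.biomass_min) & (biomass <= config.biomass_max)
        accepted.append(counts[keep])
        n_acc += int(keep.sum())
        n_drawn += batch

    counts = np.concatenate(accepted)[: config.n_candidates]
    p = counts / counts.sum(axis=1, keepdims=True)
    cloud = pd.DataFrame(counts, columns=[f"n_{sid}" for sid in pool.ids])
    cloud["biomass_g"] = np.round(_raw_biomass_g(counts, masses), 6)
    cloud["cwm"] = p @ rates
    cloud["fdiv_rao"] = np.einsum("ni,ij,nj->n", p, dmat, p)
    cloud["richness"] = (counts > 0).sum(axis=1)
    return CandidateCloud(table=cloud, species_ids=pool.ids)


def corner_scores(
    cwm_values: np.ndarray, fdiv_values: np.ndarray, corners: Sequence[str] = CORNERS
) -> pd.DataFrame:
    """Per-candidate corner scores from marginal rank fractions.

    Each candidate gets rank fractions r_cwm, r_fdiv in (0, 1) over the
    cloud; a corner's score is ``min`` of the two signed fractions (H
    keeps r, L uses 1 - r), so a score near 1 means the candidate sits
    deep in that corner of the CWM-FD plane.
    """
    from scipy.stats import rankdata

    n = len(cwm_values)
    r_c = (rankdata(cwm_values) - 0.5) / n
    r_f = (rankdata(fdiv_values) - 0.5) / n
    cols = {}
    for corner in corners:
        sc = r_c if corner[0] == "H" else 1.0 - r_c
        sf = r_f if corner[1] == "H" else 1.0 - r_f
        cols[corner] = np.minimum(sc, sf)
    return pd.DataFrame(cols)


def classify_corners(cloud: CandidateCloud, config: DesignConfig) -> CandidateCloud:
    """Label the cloud's most distinct CWM-FD corner combinations.

    CWM and FD are hump-dependent, so the joint upper-quantile box of the
    marginals is typically unoccupied; corners are instead defined by a
    rank-based corner score (see :func:`corner_scores`). Each candidate is
    assigned to its best-scoring corner and only the most extreme
    ``corner_quantile`` fraction of each corner region keeps the label;
    the rest stay unlabeled. Ties between corners resolve in the order of
    ``config.corners``, which leaves degenerate clouds (e.g. perfectly
    rank-correlated cwm and fdiv) with empty mixed corners.
    """
    if len(cloud) == 0:
        raise ValueError("empty candidate cloud")
    t = cloud.table
    scores = corner_scores(
        t["cwm"].to_numpy(), t["fdiv_rao"].to_numpy(), config.corners
    )
    best = scores.to_numpy().argmax(axis=1)  # first corner wins ties
    best_score = scores.to_numpy().max(axis=1)
    corner = pd.Series(pd.NA, index=t.index, dtype="object")
    occupancy = {}
    for ci, name in enumerate(config.corners):
        in_region = best == ci
        occupancy[name] = int(in_region.sum())
        if occupancy[name] == 0:
            continue
        thr = np.quantile(best_score[in_region], 1.0 - config.corner_quantile)
        sel = in_region & (best_score >= thr)
        corner[np.flatnonzero(sel)] = name
        occupancy[name] = int(sel.sum())
    empty = [c for c, n in occupancy.items() if n == 0]
    if empty:
        raise ValueError(
            f"empty corner(s) {empty} (occupancy {occupancy}): increase "
            "n_candidates or widen corner_quantile"
        )
    t = t.copy()
    t["corner"] = corner
    return CandidateCloud(table=t, species_ids=cloud.species_ids)


def select_design(cloud: CandidateCloud, config: DesignConfig) -> Design:
    """Draw compositionally distinct assemblages from each labeled corner.

    Within each corner candidates are taken in seeded random order and a
    candidate is rejected if its Bray-Curtis distance (on count vectors)
    to *any* already-selected assemblage, in any corner, falls below
    ``min_composition_distance``. Identical count vectors have distance 0,
    so exact duplicates can never be selected twice.

    The greedy draw can paint itself into a corner (an early pick may
    block every remaining candidate of a later corner), so the whole
    selection is restarted with a fresh seeded shuffle up to a bounded
    number of times before giving up.
    """
    if "corner" not in cloud.table.columns:
        raise ValueError("cloud is unlabeled: run classify_corners first")
    counts_all = cloud.counts_matrix()
    max_restarts = 50
    failure: str | None = None
    for attempt in range(max_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, attempt)))
        chosen_rows: list[int] = []
        chosen_corner: list[str] = []
        complete = True
        for corner in config.corners:
            idx = np.flatnonzero((cloud.table["corner"] == corner).to_numpy())
            if idx.size == 0:
                raise ValueError(f"corner {corner} is empty")
            rng.shuffle(idx)
            n_taken = 0
            for row in idx:
                if n_taken >= config.assemblages_per_corner:
                    break
                v = counts_all[row]
                if any(
                    braycurtis(v, counts_all[r]) < config.min_composition_distance
                    for r in chosen_rows
                ):
                    continue
                chosen_rows.append(int(row))
                chosen_corner.append(corner)
                n_taken += 1
            if n_taken < config.assemblages_per_corner:
                failure = (
                    f"corner {corner}: only {n_taken}/{config.assemblages_per_corner} "
                    f"assemblages satisfy the composition-distance rule "
                    f"(candidates in corner: {idx.size}); partial design "
                    f"{[f'{c}:{r}' for r, c in zip(chosen_rows, chosen_corner)]}"
                )
                complete = False
                break
        if complete:
            break
    else:
        raise RuntimeError(
            f"selection failed after {max_restarts} restarts; last attempt: {failure}"
        )
    sel = cloud.table.iloc[chosen_rows].copy().reset_index(drop=True)
    sel["corner"] = chosen_corner
    per_corner_counter: dict[str, int] = {}
    ids = []
    for c in chosen_corner:
        per_corner_counter[c] = per_corner_counter.get(c, 0) + 1
        ids.append(f"{c}{per_corner_counter[c]}")
    sel.insert(0, "assemblage_id", ids)
    design = Design(
        selected=sel,
        config=config,
        species_ids=cloud.species_ids,
        provenance={"seed": config.seed, "n_candidates_generated": len(cloud)},
    )
    _check_corner_contrast(design)
    return design


def _check_corner_contrast(design: Design) -> None:
    """Assert the selected corners are ordered as labeled."""
    t = design.selected
    high_c = t.loc[t["corner"].isin(["HH", "HL"]), "cwm"].mean()
    low_c = t.loc[t["corner"].isin(["LH", "LL"]), "cwm"].mean()
    high_f = t.loc[t["corner"].isin(["HH", "LH"]), "fdiv_rao"].mean()
    low_f = t.loc[t["corner"].isin(["HL", "LL"]), "fdiv_rao"].mean()
    if not (high_c > low_c and high_f > low_f):
        raise RuntimeError(
            "selected design lost its corner contrast: "
            f"CWM {high_c:.4f} vs {low_c:.4f}, FDiv {high_f:.4f} vs {low_f:.4f}"
        )


def run_design(
    pool: SpeciesPool, config: DesignConfig | None = None, trait: str = "consumption_rate"
) -> Design:
    """Full pipeline: simulate candidates, classify corners, select the design."""
    config = config or DesignConfig()
    cloud = simulate_candidates(pool, config, trait=trait)
    labeled = classify_corners(cloud, config)
    return select_design(labeled, config)
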