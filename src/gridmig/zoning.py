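"""Urban-extent delineation and socioclimatic binning.

Urban extents are delineated per country-year purely from population
density rank: given a country's total population and its urban population
share (UN WUP-style), cells are taken in descending density order until
the cumulative population count meets the urban population target.  The
cell that crosses the target is included.  By construction the sparsest
urban cell is at least as dense as the densest rural cell.

Socioclimatic bins stratify the inhabited world into 100 zones of similar
human development and dryness: ten population-weighted deciles of HDI,
each subdivided into ten population-weighted deciles of aridity.  Bin id
= 10 × HDI decile + aridity decile, so the driest cells of the least
developed decile land in bin 0.  Each bin holds ~1% of total population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as _classify


@dataclass(frozen=True)
class UrbanTarget:
    """Country-year urban population target: urbanPop = totPop × share."""

    tot_pop: float
    shr_urban_pop: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.shr_urban_pop <= 1.0:
            raise ValueError(f"urban share must be in [0,1], got {self.shr_urban_pop}")

    @property
    def urban_pop(self) -> float:
        return self.tot_pop * self.shr_urban_pop


def urban_mask(
    population: np.ndarray,
    density_rank_field: np.ndarray,
    target: UrbanTarget,
    *,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Binary urban mask (1 urban, 0 rural) for one country-year.

    Cells (restricted to ``valid`` if given) are sorted by
    ``density_rank_field`` descending — ties broken by raw population then
    cell index for determinism — and accumulated until the cumulative
    population meets ``target.urban_pop``; the crossing cell is included.
    Zero-population cells can never be urban (they contribute nothing to
    the cumulative count and a zero-share country has no urban cells).
    """
    pop = np.asarray(population, dtype=float)
    dens = np.asarray(density_rank_field, dtype=float)
    mask = np.zeros(pop.shape, dtype=np.uint8)
    sel = (pop > 0) if valid is None else ((pop > 0) & valid)
    if target.urban_pop <= 0 or not sel.any():
        return mask
    idx = np.nonzero(sel.ravel())[0]
    # lexsort: last key is primary; negate for descending order
    order = np.lexsort((idx, -pop.ravel()[idx], -dens.ravel()[idx]))
    ranked = idx[order]
    cum = np.cumsum(pop.ravel()[ranked])
    # first position where the cumulative count meets the target (inclusive)
    n_urban = int(np.searchsorted(cum, target.urban_pop, side="left")) + 1
    n_urban = min(n_urban, ranked.size)
    flat = mask.ravel()
    flat[ranked[:n_urban]] = 1
    return flat.reshape(mask.shape)


def urban_mask_by_country(
    population: np.ndarray,
    density_rank_field: np.ndarray,
    country_labels: np.ndarray,
    shares: dict[int, float],
) -> np.ndarray:
    """Apply :func:`urban_mask` independently within each country."""
    out = np.zeros(population.shape, dtype=np.uint8)
    for cid, shr in shares.items():
        sel = country_labels == cid
        if not sel.any():
            continue
        tot = float(np.asarray(population, dtype=float)[sel].sum())
        m = urban_mask(population, density_rank_field, UrbanTarget(tot, shr), valid=sel)
        out |= m
    return out


def weighted_deciles(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Assign each element a population-weighted decile in 0..9.

    Elements are sorted by (value, index); the decile of an element is
    determined by the cumulative weight of strictly preceding elements
    relative to ten equal-weight bounds, so ties and lumpy weights resolve
    deterministically and the partition is exhaustive.
    """
    v = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if v.size == 0:
        return np.zeros(0, dtype=np.int64)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    order = np.lexsort((np.arange(v.size), v))
    cum_before = np.concatenate(([0.0], np.cumsum(w[order])[:-1]))
    dec_sorted = np.minimum((10.0 * cum_before / total).astype(np.int64), 9)
    dec = np.empty(v.size, dtype=np.int64)
    dec[order] = dec_sorted
    return dec


@dataclass
class SocioclimaticBins:
    """Cell → bin id (0..99) over the valid-cell mask; −1 elsewhere."""

    bin_id: np.ndarray  # int raster, −1 outside the partition
    valid: np.ndarray   # bool raster of binned cells

    def population_shares(self, population: np.ndarray) -> np.ndarray:
        """Fraction of binned population in each of the 100 bins."""
        pop = np.asarray(population, dtype=float)
        shares = np.zeros(100)
        ids = self.bin_id[self.valid]
        np.add.at(shares, ids, pop[self.valid])
        return shares / shares.sum()


def assign_bins(
    hdi: np.ndarray,
    aridity: np.ndarray,
    population: np.ndarray,
) -> SocioclimaticBins:
    """Nested population-weighted decile binning: HDI-major, aridity-minor.

    Only populated cells with finite covariates are binned; the HDI decile
    is computed over all such cells, then each HDI decile is subdivided
    into aridity deciles using the same weighting.
    """
    hdi = np.asarray(hdi, dtype=float)
    aridity = np.asarray(aridity, dtype=float)
    pop = np.asarray(population, dtype=float)
    valid = (pop > 0) & np.isfinite(hdi) & np.isfinite(aridity)
    bin_id = np.full(hdi.shape, -1, dtype=np.int64)
    if not valid.any():
        return SocioclimaticBins(bin_id=bin_id, valid=valid)
    flat_idx = np.nonzero(valid.ravel())[0]
    h = hdi.ravel()[flat_idx]
    a = aridity.ravel()[flat_idx]
    w = pop.ravel()[flat_idx]
    hdec = weighted_deciles(h, w)
    bins = np.empty(flat_idx.size, dtype=np.int64)
    for d in range(10):
        sub = hdec == d
        if not sub.any():
            continue
        adec = weighted_deciles(a[sub], w[sub])
        bins[sub] = 10 * d + adec
    bin_id.ravel()[flat_idx] = bins
    return SocioclimaticBins(bin_id=bin_id, valid=valid)


def bin_statistics(
    bins: SocioclimaticBins,
    net_migration_total: np.ndarray,
    urban: np.ndarray,
    population: np.ndarray,
) -> pd.DataFrame:
    """Per-bin urban and rural net-migration rates over the full period.

    ``net_migration_total`` is the accumulated (summed over years) net
    migration per cell; ``population`` the reference population used both
    for binning weights and rate denominators.  Rates are net migrants per
    1,000 urban (resp. rural) persons; a bin with no urban (rural)
    population gets NaN there, flagged in ``urban_defined``.
    """
    pop = np.asarray(population, dtype=float)
    mig = np.asarray(net_migration_total, dtype=float)
    urb = np.asarray(urban).astype(bool)
    rows = []
    ids = bins.bin_id
    for b in range(100):
        sel = bins.valid & (ids == b)
        u = sel & urb
        r = sel & ~urb
        upop, rpop = pop[u].sum(), pop[r].sum()
        umig, rmig = mig[u].sum(), mig[r].sum()
        rows.append(
            {
                "bin": b,
                "hdi_decile": b // 10,
                "aridity_decile": b % 10,
                "population": pop[sel].sum(),
                "urban_pop": upop,
                "rural_pop": rpop,
                "net_mgr": mig[sel].sum(),
                "urban_mgr": umig,
                "rural_mgr": rmig,
                "urban_rate_per_1000": 1000.0 * umig / upop if upop > 0 else np.nan,
                "rural_rate_per_1000": 1000.0 * rmig / rpop if rpop > 0 else np.nan,
                "urban_defined": upop > 0,
                "rural_defined": rpop > 0,
                "direction": _classify.direction_class(umig, rmig).value,
            }
        )
    return pd.DataFrame(rows)
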