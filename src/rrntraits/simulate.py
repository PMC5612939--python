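"""Synthetic community, stream-group and growth-curve generators.

These generators produce every input the pipeline consumes — OTU count
tables with sample metadata, a taxonomy map, a copy-number lookup, and
cell-count growth curves — with the statistical structure a biofilm
succession experiment exhibits: a genus-structured community whose rank
abundances follow a geometric series, counts drawn Dirichlet-multinomial
(rarefied amplicon tables are overdispersed multinomials), replicated
time series under contrasting trophic regimes, and an early
high-copy-number enrichment in the eutrophic regime that decays over the
initial colonization phase.

Ground truth (expected bin proportions per sample, the true copy number
of every OTU) is always emitted alongside the data so that tests never
re-derive truth from the generated tables. All generators are
bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthCurve, zwietering_logistic
from .io_tables import OtuTable
from .rrn import RrnLookup
from .traits import HCN_RANGE

__all__ = [
    "RegimeSpec",
    "SuccessionConfig",
    "StreamGroupSpec",
    "StreamGroupConfig",
    "generate_succession",
    "generate_streams",
    "generate_growth_curves",
]

# rrn-class spectrum mirroring stream biofilm communities: dominated by
# rrn-2 genera, LCN-heavy, with a thin HCN tail up to 15.
DEFAULT_RRN_SPECTRUM = {
    1: 8, 2: 16, 3: 14, 4: 6, 5: 6, 6: 3, 7: 1, 8: 1, 9: 3, 10: 1, 15: 1,
}


@dataclass
class RegimeSpec:
    """One trophic regime of the succession experiment.

    ``hcn_boost_initial`` multiplies HCN genus abundances by
    ``1 + boost * exp(-decay_rate * t)`` before renormalization;
    a boost of 0 yields a regime with no time-bin interaction (null).
    """

    name: str
    hcn_boost_initial: float = 0.0
    phase_cut: float = 25.0
    decay_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.hcn_boost_initial < 0 or self.decay_rate < 0:
            raise ValueError("boost and decay must be non-negative")


@dataclass
class SuccessionConfig:
    """Defaults mirror the study design: two regimes (oligotrophic null,
    eutrophic with an initial HCN boost), 3 replicates, 7 time points over
    a 45-day experiment, 10^4 reads per sample."""

    n_genera: int = 60
    rrn_spectrum: dict = field(default_factory=lambda: dict(DEFAULT_RRN_SPECTRUM))
    otus_per_genus: int = 3
    time_points: tuple = (4.0, 11.0, 18.0, 25.0, 32.0, 39.0, 45.0)
    n_replicates: int = 3
    regimes: tuple = (
        RegimeSpec("oligotrophic", hcn_boost_initial=0.0),
        # decay e-folding time equals the initial succession phase (25 d):
        # the enrichment is substantial throughout that phase and minor after
        RegimeSpec("eutrophic", hcn_boost_initial=1.0, decay_rate=1.0 / 25.0),
    )
    depth: int = 10_000
    overdispersion: float = 200.0
    geometric_k: float = 0.92  # rank-abundance retention ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.rrn_spectrum.values()) != self.n_genera:
            raise ValueError("rrn_spectrum must sum to n_genera")
        if not 0 < self.geometric_k < 1:
            raise ValueError("geometric_k must lie in (0, 1)")


@dataclass
class StreamGroupSpec:
    """One stream habitat group; ``mean_rrn_shift`` scales HCN genus
    abundances by (1 + shift), statically (no time decay)."""

    name: str
    mean_rrn_shift: float = 0.0


@dataclass
class StreamGroupConfig:
    """Two-habitat comparison; sample sizes default to the glacier-fed
    (26) vs headwater (50) design."""

    groups: tuple = (
        StreamGroupSpec("glacier-fed", mean_rrn_shift=1.0),
        StreamGroupSpec("headwater", mean_rrn_shift=0.0),
    )
    n_samples: tuple = (26, 50)
    n_genera: int = 60
    rrn_spectrum: dict = field(default_factory=lambda: dict(DEFAULT_RRN_SPECTRUM))
    otus_per_genus: int = 3
    depth: int = 10_000
    overdispersion: float = 200.0
    geometric_k: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 2 or len(self.n_samples) != 2:
            raise ValueError("exactly two stream groups are required")
        if sum(self.rrn_spectrum.values()) != self.n_genera:
            raise ValueError("rrn_spectrum must sum to n_genera")


def _community_skeleton(rng, n_genera, rrn_spectrum, otus_per_genus, geometric_k):
    """Shared machinery: genus names, true rrn, base abundances, OTU split."""
    genera = [f"genus_{i:03d}" for i in range(1, n_genera + 1)]
    rrn_values = np.repeat(
        [int(c) for c in sorted(rrn_spectrum)],
        [rrn_spectrum[c] for c in sorted(rrn_spectrum)],
    )
    rng.shuffle(rrn_values)
    genus_rrn = dict(zip(genera, (int(v) for v in rrn_values)))
    # geometric-series rank abundances, ranks assigned at random so that
    # abundance is not systematically tied to copy number
    ranks = rng.permutation(n_genera)
    base = geometric_k ** ranks.astype(float)
    base /= base.sum()
    genus_base = dict(zip(genera, base))
    # rrnDB-style genus means: integer truth plus a sub-half offset so the
    # rounding step is exercised without changing the true integer
    lookup_means = {
        g: genus_rrn[g] + float(rng.uniform(-0.45, 0.45)) for g in genera
    }
    lookup_means = {g: max(m, 0.55) for g, m in lookup_means.items()}
    taxonomy = {}
    otu_ids: dict = {}
    split: dict = {}
    for g in genera:
        ids = [f"{g}_otu{j}" for j in range(1, otus_per_genus + 1)]
        otu_ids[g] = ids
        w = rng.dirichlet(np.full(otus_per_genus, 5.0))
        split[g] = w
        for oid in ids:
            taxonomy[oid] = g
    return genera, genus_rrn, genus_base, lookup_means, taxonomy, otu_ids, split


def _sample_counts(rng, otu_props, depth, overdispersion):
    alpha = np.maximum(otu_props * overdispersion, 1e-9)
    p = rng.dirichlet(alpha)
    return rng.multinomial(depth, p)


def _expected_bins(genera, genus_rrn, props):
    lcn = sum(p for g, p in zip(genera, props) if genus_rrn[g] < HCN_RANGE[0])
    hcn = sum(p for g, p in zip(genera, props) if genus_rrn[g] >= HCN_RANGE[0])
    return float(lcn), float(hcn)


def generate_succession(config: SuccessionConfig):
    """Simulate the two-regime succession experiment.

    Returns ``(tables, taxonomy, lookup, truth)``: one OtuTable per
    regime with time/replicate/group metadata, the OTU->genus map, an
    RrnLookup whose rounded values equal the true copy numbers, and a
    ground-truth record with each sample's expected LCN/HCN proportions
    and HCN:LCN ratio plus the true rrn of every OTU.
    """
    rng = np.random.default_rng(config.seed)
    genera, genus_rrn, genus_base, means, taxonomy, otu_ids, split = _community_skeleton(
        rng, config.n_genera, config.rrn_spectrum, config.otus_per_genus,
        config.geometric_k,
    )
    lookup = RrnLookup(means)
    all_otus = [oid for g in genera for oid in otu_ids[g]]
    truth = {
        "otu_rrn": {oid: genus_rrn[taxonomy[oid]] for oid in all_otus},
        "genus_rrn": dict(genus_rrn),
        "genus_base": dict(genus_base),
        "samples": {},
    }
    tables = []
    base = np.array([genus_base[g] for g in genera])
    is_hcn = np.array([genus_rrn[g] >= HCN_RANGE[0] for g in genera])
    for regime in config.regimes:
        cols = {}
        meta_rows = []
        for t in config.time_points:
            boost = 1.0 + regime.hcn_boost_initial * np.exp(-regime.decay_rate * t)
            props = base * np.where(is_hcn, boost, 1.0)
            props = props / props.sum()
            lcn_e, hcn_e = _expected_bins(genera, genus_rrn, props)
            otu_props = np.concatenate([props[i] * split[g] for i, g in enumerate(genera)])
            for rep in range(1, config.n_replicates + 1):
                sid = f"{regime.name}_t{int(t):02d}_r{rep}"
                cols[sid] = _sample_counts(rng, otu_props, config.depth,
                                           config.overdispersion)
                meta_rows.append({"sample_id": sid, "time_days": float(t),
                                  "replicate": f"r{rep}", "group": regime.name})
                truth["samples"][sid] = {
                    "lcn_expected": lcn_e,
                    "hcn_expected": hcn_e,
                    "ratio_expected": hcn_e / lcn_e if lcn_e > 0 else float("nan"),
                }
        counts = pd.DataFrame(cols, index=all_otus, dtype=np.int64)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        tables.append(OtuTable(counts, meta))
    return tables, taxonomy, lookup, truth


def generate_streams(config: StreamGroupConfig):
    """Simulate the two-habitat stream comparison (static HCN shift)."""
    rng = np.random.default_rng(config.seed)
    genera, genus_rrn, genus_base, means, taxonomy, otu_ids, split = _community_skeleton(
        rng, config.n_genera, config.rrn_spectrum, config.otus_per_genus,
        config.geometric_k,
    )
    lookup = RrnLookup(means)
    all_otus = [oid for g in genera for oid in otu_ids[g]]
    truth = {
        "otu_rrn": {oid: genus_rrn[taxonomy[oid]] for oid in all_otus},
        "genus_rrn": dict(genus_rrn),
        "samples": {},
    }
    base = np.array([genus_base[g] for g in genera])
    is_hcn = np.array([genus_rrn[g] >= HCN_RANGE[0] for g in genera])
    tables = []
    for group, n_samp in zip(config.groups, config.n_samples):
        props = base * np.where(is_hcn, 1.0 + group.mean_rrn_shift, 1.0)
        props = props / props.sum()
        lcn_e, hcn_e = _expected_bins(genera, genus_rrn, props)
        otu_props = np.concatenate([props[i] * split[g] for i, g in enumerate(genera)])
        cols = {}
        meta_rows = []
        for k in range(1, n_samp + 1):
            sid = f"{group.name}_s{k:03d}"
            cols[sid] = _sample_counts(rng, otu_props, config.depth,
                                       config.overdispersion)
            meta_rows.append({"sample_id": sid, "group": group.name})
            truth["samples"][sid] = {"lcn_expected": lcn_e, "hcn_expected": hcn_e}
        counts = pd.DataFrame(cols, index=all_otus, dtype=np.int64)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        tables.append(OtuTable(counts, meta))
    return tables, taxonomy, lookup, truth


def generate_growth_curves(
    A: float = 100.0,
    mu_max: float = 5.0,
    lag: float = 2.0,
    noise_sd: float = 5.0,
    times=None,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Noisy logistic growth curves plus their ground-truth parameters.

    Values are the Zwietering logistic at the requested times plus i.i.d.
    Gaussian noise, truncated at zero (counts cannot be negative).
    """
    if A <= 0 or mu_max <= 0 or lag < 0:
        raise ValueError("require A > 0, mu_max > 0, lag >= 0")
    if times is None:
        times = np.linspace(0.0, 20.0, 20)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    clean = zwietering_logistic(times, A, mu_max, lag)
    curves = []
    for rep in range(1, n_replicates + 1):
        noisy = np.maximum(clean + rng.normal(0.0, noise_sd, size=len(times)), 0.0) \
            if noise_sd > 0 else clean.copy()
        curves.append(GrowthCurve(times, noisy, label=f"rep{rep}"))
    truth = {"A": A, "mu_max": mu_max, "lag": lag, "noise_sd": noise_sd}
    return curves, truth
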