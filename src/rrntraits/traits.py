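"""Community-aggregated copy-number trait statistics.

Taxa are binned by integer rrn copy number into low-copy-number (LCN,
rrn 1-3, slow-but-efficient strategists) and high-copy-number (HCN,
rrn 4-15, fast-but-inefficient strategists); the two ranges partition the
biological range [1, 15]. Per sample the module computes the summed
relative abundances of each bin, their ratio HCN:LCN, the
community-weighted mean copy number (abundance weighting), the unweighted
mean over taxa present, and the number of distinct genera per bin. Across
a succession experiment the per-time-point replicate means form a trait
trajectory split into an initial and a late phase at a configurable day
cut (default 25 d, inclusive).

By default proportions are renormalized over the assigned core-genus OTUs
before binning, so LCN + HCN abundances partition unity and the ratio is
insensitive to the discarded (unassignable) fraction; a whole-table
denominator is available via ``renormalize=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import OtuTable, RelAbundanceTable, UNASSIGNED, normalize_genus, relative_abundance
from .rrn import RRN_MAX, RRN_MIN, RrnAssignment, RrnLookup, assign_rrn

__all__ = [
    "LCN_RANGE",
    "HCN_RANGE",
    "TraitProfile",
    "bin_rrn",
    "core_genera",
    "trait_profile",
    "trait_profiles",
    "genera_ratio",
    "trajectory",
    "rrn_class_abundance",
]

LCN_RANGE = (1, 3)
HCN_RANGE = (4, 15)


def classify_rrn(copies: int) -> str:
    """Bin an integer copy number: "LCN" for 1-3, "HCN" for 4-15."""
    if not RRN_MIN <= copies <= RRN_MAX:
        raise ValueError(f"copy number {copies} outside [{RRN_MIN},{RRN_MAX}]")
    return "LCN" if copies <= LCN_RANGE[1] else "HCN"


def bin_rrn(assignment: RrnAssignment) -> dict:
    """Map every assigned OTU to its bin; unassigned OTUs are excluded."""
    return {oid: classify_rrn(c) for oid, c in assignment.copies.items()}


def core_genera(tables, min_count: int = 1, min_prevalence: int = 1):
    """Intersect genus sets across datasets to find the shared core.

    Parameters
    ----------
    tables
        List of ``(OtuTable, taxonomy)`` pairs; a genus is present in a
        dataset when at least one of its OTUs reaches ``min_count`` reads
        in at least ``min_prevalence`` samples.

    Returns
    -------
    (core, fractions)
        ``core`` is the genus-set intersection (normalized names);
        ``fractions`` lists, per input table, the fraction of its OTUs
        belonging to core genera.
    """
    if not tables:
        raise ValueError("need at least one (table, taxonomy) pair")
    genus_sets = []
    for table, taxonomy in tables:
        present = set()
        hits = (table.counts >= min_count).sum(axis=1)
        for oid in table.otu_ids:
            if hits[oid] >= min_prevalence:
                g = normalize_genus(taxonomy.get(oid, UNASSIGNED))
                if g != UNASSIGNED:
                    present.add(g)
        genus_sets.append(present)
    core = set.intersection(*genus_sets)
    if not core:
        warnings.warn("core genus intersection is empty", UserWarning, stacklevel=2)
    fractions = []
    for table, taxonomy in tables:
        n = len(table.otu_ids)
        in_core = sum(
            1 for oid in table.otu_ids
            if normalize_genus(taxonomy.get(oid, UNASSIGNED)) in core
        )
        fractions.append(in_core / n if n else 0.0)
    return core, fractions


@dataclass
class TraitProfile:
    """Per-sample aggregated copy-number trait values.

    ``ratio_hcn_lcn`` is NaN with ``defined=False`` when LCN abundance is
    zero (never +inf) or when the sample has no assigned abundance at all.
    """

    sample_id: object
    lcn_abund: float
    hcn_abund: float
    ratio_hcn_lcn: float
    cwm_rrn_abundance: float
    mean_rrn_presence: float
    n_genera_lcn: int
    n_genera_hcn: int
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "lcn_abund": self.lcn_abund,
            "hcn_abund": self.hcn_abund,
            "ratio_hcn_lcn": self.ratio_hcn_lcn,
            "cwm_rrn_abundance": self.cwm_rrn_abundance,
            "mean_rrn_presence": self.mean_rrn_presence,
            "n_genera_lcn": self.n_genera_lcn,
            "n_genera_hcn": self.n_genera_hcn,
            "defined": self.defined,
        }


def _undefined_profile(sample_id) -> TraitProfile:
    nan = float("nan")
    return TraitProfile(sample_id, nan, nan, nan, nan, nan, 0, 0, defined=False)


def trait_profile(
    rel: RelAbundanceTable,
    assignment: RrnAssignment,
    taxonomy: dict,
    sample_id,
    genus_collapse_presence: bool = False,
) -> TraitProfile:
    """Aggregate one sample's proportions into a :class:`TraitProfile`.

    ``rel`` is expected to hold proportions over assigned OTUs (typically
    renormalized over the assigned core subset). The abundance-weighted
    community mean is sum(p_i * rrn_i); the presence mean averages rrn over
    OTUs with p_i > 0 (or over distinct genera present when
    ``genus_collapse_presence`` is set, since a database mean is a genus
    attribute and OTU-level averaging weights genera by OTU richness).
    """
    if sample_id not in rel.props.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    col = rel.props[sample_id]
    otus = [oid for oid in col.index if oid in assignment.copies]
    p = np.array([col[oid] for oid in otus], dtype=float)
    total = p.sum()
    if not otus or total <= 0:
        return _undefined_profile(sample_id)
    rrn = np.array([assignment.copies[oid] for oid in otus], dtype=float)
    is_hcn = rrn >= HCN_RANGE[0]
    lcn = float(p[~is_hcn].sum())
    hcn = float(p[is_hcn].sum())
    ratio = hcn / lcn if lcn > 0 else float("nan")
    cwm = float((p * rrn).sum() / total)
    present = p > 0
    if genus_collapse_presence:
        seen: dict = {}
        for oid, r, pres in zip(otus, rrn, present):
            if pres:
                seen[normalize_genus(taxonomy.get(oid, UNASSIGNED))] = r
        mean_presence = float(np.mean(list(seen.values()))) if seen else float("nan")
    else:
        mean_presence = float(rrn[present].mean()) if present.any() else float("nan")
    genera_lcn = {
        normalize_genus(taxonomy.get(oid, UNASSIGNED))
        for oid, h, pres in zip(otus, is_hcn, present) if pres and not h
    }
    genera_hcn = {
        normalize_genus(taxonomy.get(oid, UNASSIGNED))
        for oid, h, pres in zip(otus, is_hcn, present) if pres and h
    }
    return TraitProfile(
        sample_id=sample_id,
        lcn_abund=lcn,
        hcn_abund=hcn,
        ratio_hcn_lcn=ratio,
        cwm_rrn_abundance=cwm,
        mean_rrn_presence=mean_presence,
        n_genera_lcn=len(genera_lcn),
        n_genera_hcn=len(genera_hcn),
        defined=True,
    )


def trait_profiles(
    table: OtuTable,
    taxonomy: dict,
    lookup: RrnLookup,
    core=None,
    renormalize: bool = True,
    genus_collapse_presence: bool = False,
) -> pd.DataFrame:
    """End-to-end per-sample trait table for one OTU table.

    Subsets to assigned OTUs (optionally restricted to ``core`` genera),
    computes proportions (renormalized over that subset by default), and
    returns one row per sample with all trait fields joined to the
    sample metadata.
    """
    assignment = assign_rrn(table, taxonomy, lookup)
    keep = [oid for oid in table.otu_ids if oid in assignment.copies]
    if core is not None:
        core_norm = {normalize_genus(g) for g in core}
        keep = [oid for oid in keep if normalize_genus(taxonomy.get(oid, UNASSIGNED)) in core_norm]
    if not keep:
        raise ValueError("no assigned OTUs to profile")
    rel = relative_abundance(table, subset=keep, renormalize=renormalize)
    rows = [
        trait_profile(rel, assignment, taxonomy, sid,
                      genus_collapse_presence=genus_collapse_presence).as_dict()
        for sid in table.sample_ids
    ]
    df = pd.DataFrame(rows).set_index("sample_id")
    return df.join(table.sample_meta)


def genera_ratio(n_hcn: float, n_lcn: float) -> float:
    """Ratio of HCN to LCN genus counts (replicate means admissible).

    Returns NaN when the LCN count is zero.
    """
    if n_hcn < 0 or n_lcn < 0:
        raise ValueError("genus counts must be non-negative")
    if n_lcn == 0:
        return float("nan")
    return n_hcn / n_lcn


def trajectory(
    profiles: pd.DataFrame,
    field: str = "ratio_hcn_lcn",
    phase_cut: float = 25.0,
) -> pd.DataFrame:
    """Replicate mean +/- sd of a trait field per time point, phase-labeled.

    Each time point at ``time_days <= phase_cut`` is labeled "initial"
    (the cut is inclusive), otherwise "late". Undefined (NaN) replicate
    values reduce n for that time point with a warning; the sd of a single
    replicate is 0.
    """
    if field not in profiles.columns:
        raise KeyError(f"unknown field {field!r}")
    if profiles["time_days"].isna().any():
        raise ValueError("every sample needs time_days metadata")
    if profiles["replicate"].isna().any():
        raise ValueError("every sample needs replicate metadata")
    rows = []
    for t, grp in profiles.groupby("time_days"):
        vals = grp[field].astype(float)
        n_total = len(vals)
        vals = vals.dropna()
        if len(vals) < n_total:
            warnings.warn(
                f"{n_total - len(vals)} undefined {field!r} value(s) at day {t}; reduced n",
                UserWarning,
                stacklevel=2,
            )
        mean = float(vals.mean()) if len(vals) else float("nan")
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({
            "time_days": float(t),
            "mean": mean,
            "sd": sd,
            "n": int(len(vals)),
            "phase": "initial" if t <= phase_cut else "late",
        })
    out = pd.DataFrame(rows).sort_values("time_days").reset_index(drop=True)
    if not out["time_days"].is_monotonic_increasing or out["time_days"].duplicated().any():
        raise ValueError("time points must be strictly increasing")
    return out


def rrn_class_abundance(
    rel: RelAbundanceTable,
    assignment: RrnAssignment,
) -> pd.DataFrame:
    """Summed relative abundance per integer copy-number class per sample.

    The per-rrn-value table behind class-trajectory plots; rows are copy
    numbers 1-15, columns are samples.
    """
    idx = range(RRN_MIN, RRN_MAX + 1)
    out = pd.DataFrame(0.0, index=idx, columns=rel.props.columns)
    for oid, c in assignment.copies.items():
        if oid in rel.props.index:
            out.loc[c] += rel.props.loc[oid]
    out.index.name = "rrn"
    return out
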