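"""Reducers for the non-image assays: TAG, lipidomics, qPCR, survival.

* TAG: assays pool whole flies (3 per biological replicate); values are
  normalized to µg TAG per fly, and starvation response is the drop from
  the fed mean (Δ-TAG) or the starved mean as a fraction of the fed
  control.
* Lipidomics: species concentrations (e.g. "PE 36.2") are summed into
  class totals per replicate; class tables feed a diet x day two-way
  ANOVA with Šidák post-tests, or a Welch t test for two-genotype
  designs. Instrument units are carried opaquely — every downstream
  statistic is unit-covariant.
* qPCR: comparative-CT (Livak) relative quantification against a
  reference gene and a control group; fold change = 2^−ΔΔCt.
* Survival: long death-day tables are reshaped for the Mantel–Cox
  log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as fqstats

__all__ = [
    "TagRecord",
    "tag_per_fly",
    "delta_tag",
    "aggregate_lipid_classes",
    "compare_lipid_classes",
    "ddct_fold_change",
    "survival_arrays",
]

LIPID_CLASSES = ("TAG", "DAG", "FFA", "PE", "PC", "LPE", "LPC", "SM", "CE")


@dataclass
class TagRecord:
    """One TAG assay replicate: a pool of ``n_flies`` whole flies."""

    replicate: str
    n_flies: int
    total_tag: float         # µg in the pooled homogenate
    diet: str = "NF"
    day: int = 14
    state: str = "fed"       # "fed" or "stv" (optionally with hours, e.g. "stv16")

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.total_tag < 0:
            raise ValueError("total_tag must be >= 0")


def tag_per_fly(rec: TagRecord) -> float:
    """TAG normalized per fly: total µg divided by flies in the pool."""
    return rec.total_tag / rec.n_flies


def delta_tag(fed: list[TagRecord], stv: list[TagRecord]):
    """Starvation-induced TAG change within one diet/day group.

    Returns (delta, normalized): delta = mean fed per-fly TAG minus mean
    starved per-fly TAG (µg/fly mobilized during starvation), and
    normalized = starved mean / fed-control mean (0.5 when flies broke
    down half of their fat stores). Both input groups must share diet
    and day.
    """
    if not fed or not stv:
        raise ValueError("both fed and starved groups must be non-empty")
    keys = {(r.diet, r.day) for r in fed} | {(r.diet, r.day) for r in stv}
    if len(keys) != 1:
        raise ValueError(f"mixed diet/day groups: {sorted(keys)}")
    fed_mean = float(np.mean([tag_per_fly(r) for r in fed]))
    stv_mean = float(np.mean([tag_per_fly(r) for r in stv]))
    if fed_mean == 0:
        raise ValueError("fed-control mean TAG is zero; normalization undefined")
    return fed_mean - stv_mean, stv_mean / fed_mean


# ---------------------------------------------------------------------------
# lipidomics
# ---------------------------------------------------------------------------

def _species_class(species: str) -> str:
    return species.split(" ")[0].split("(")[0]


def aggregate_lipid_classes(records: pd.DataFrame) -> pd.DataFrame:
    """Sum species concentrations into class totals per replicate.

    ``records`` columns: species, class, replicate, diet, day,
    concentration. Species names follow the "CLASS C.N" dialect
    (e.g. "PE 36.2"); a species whose prefix contradicts its class
    column is an error listing the offending names. Class totals
    conserve total concentration exactly (plain summation).
    """
    required = {"species", "class", "replicate", "diet", "day", "concentration"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["concentration"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    prefixes = records["species"].map(_species_class)
    bad = records.loc[prefixes != records["class"], "species"].unique()
    if len(bad):
        raise ValueError(f"species inconsistent with their class: {sorted(bad)}")
    out = (records.groupby(["class", "replicate", "diet", "day"], sort=True)
           ["concentration"].sum().reset_index())
    return out


def compare_lipid_classes(table: pd.DataFrame, design: str = "two_way",
                          group_col: str = "diet", alpha: float = 0.05) -> dict:
    """Per-class group comparison on an aggregated class table.

    design="two_way": diet x day ANOVA per class with Šidák-adjusted
    NF-vs-HSD contrasts within each day (the multi-day lipidomics
    design). design="welch": Welch t between the two levels of
    ``group_col`` per class, Šidák-adjusted across classes (the
    two-genotype design). Every cell needs >= 2 replicates.
    """
    results: dict = {}
    classes = sorted(table["class"].unique())
    if design == "two_way":
        for cls in classes:
            sub = table[table["class"] == cls]
            anova = fqstats.two_way_anova(sub, "concentration", group_col, "day")
            levels = sorted(sub[group_col].unique())
            if len(levels) != 2:
                raise ValueError("two_way design needs exactly 2 diet levels")
            contrasts = fqstats.pairwise_contrasts(
                anova, within="day", compare=(levels[0], levels[1]))
            results[cls] = {"anova": anova, "contrasts": contrasts}
        return results
    if design == "welch":
        m = len(classes)
        for cls in classes:
            sub = table[table["class"] == cls]
            levels = sorted(sub[group_col].unique())
            if len(levels) != 2:
                raise ValueError("welch design needs exactly 2 groups")
            a = sub.loc[sub[group_col] == levels[0], "concentration"]
            b = sub.loc[sub[group_col] == levels[1], "concentration"]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"class {cls}: need >= 2 replicates per group")
            res = fqstats.welch_t(a, b)
            res.p_adjusted = fqstats.sidak_adjust(res.p_value, m)
            res.extra["m"] = m
            results[cls] = res
        return results
    raise ValueError("design must be 'two_way' or 'welch'")


# ---------------------------------------------------------------------------
# qPCR comparative CT
# ---------------------------------------------------------------------------

def ddct_fold_change(records: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Comparative-CT relative quantification (Livak 2^−ΔΔCt).

    ``records`` columns: sample, group, ct_target, ct_reference. Per
    sample ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the control
    group's mean ΔCt; fold = 2^−ΔΔCt. The control group's geometric mean
    fold is 1 by construction. Missing Ct values are an error.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        bad = records.loc[records[["ct_target", "ct_reference"]].isna().any(axis=1),
                          "sample"].tolist()
        raise ValueError(f"missing Ct values for samples: {bad}")
    ctrl = records[records["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    out = records.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    ctrl_mean = float(out.loc[out["group"] == control_group, "delta_ct"].mean())
    out["delta_delta_ct"] = out["delta_ct"] - ctrl_mean
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def survival_arrays(table: pd.DataFrame):
    """Reshape a (fly, group, day) death table for the log-rank test.

    Returns (durations, groups, observed). An ``observed`` column (0/1)
    is honoured if present; by default every fly is an event, matching
    assays that ran until every fly had died.
    """
    required = {"fly", "group", "day"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    durations = table["day"].to_numpy(dtype=float)
    groups = table["group"].to_numpy()
    observed = (table["observed"].to_numpy(dtype=bool)
                if "observed" in table.columns
                else np.ones(len(table), dtype=bool))
    return durations, groups, observed
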