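"""End-to-end synthetic reproduction experiment: simulate → quantify → test.

One call renders synthetic inputs for every assay (nuclei stacks, FLIC
traces, puncta scenes, TAG / lipidomics / qPCR / survival tables) under
a configurable effect structure, runs the full quantification machinery,
applies the study's statistical tests, and emits a machine-readable JSON
report. Identical config + seed gives an identical report body.

Effect multipliers describe the direction of the original findings:
starved flies feed more than fed ones (hunger-driven feeding), a
high-sugar diet raises nuclear FOXO and lowers ApoII puncta, starvation
mobilizes TAG stores. Setting every multiplier to 1 yields a null run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flic as fqflic
from . import foxo as fqfoxo
from . import puncta as fqpuncta
from . import stats as fqstats
from . import synth as fqsynth
from . import tables as fqtables

__all__ = ["RunConfig", "run_end_to_end"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved parameters of one end-to-end run.

    Constants fixed by the study design: the 40 a.u. feeding-event
    threshold, the 3-hr analysis window, and alpha = 0.05. The rest are
    fixture-scale choices of this artifact, all serializable so a run
    can be reproduced from its own report.
    """

    seed: int = 0
    alpha: float = 0.05
    # feeding
    flic_threshold: float = fqflic.EVENT_THRESHOLD
    window_s: tuple[float, float] = fqflic.ANALYSIS_WINDOW_S
    event_mode: str = "runs"
    flies_per_cell: int = 12
    fed_bout_rate: float = 0.05           # bouts/min when fed
    stv_feeding_multiplier: float = 2.0   # x fed rate when starved (1 = null)
    flic_duration_s: float = 10_800.0
    flic_sampling_rate: float = 5.0
    # nuclear FOXO
    nuclei_per_group: int = 12
    nuclear_foxo_nf: float = 110.0
    foxo_multiplier: float = 1.5          # HSD nuclear FOXO vs NF (1 = null)
    foxo_noise_sd: float = 6.0
    rim_fraction: float = 0.5
    threshold_method: str = "otsu"
    anova_ss_type: str = "III"
    # puncta
    flies_per_puncta_group: int = 10
    nf_mean_puncta: float = 10.0
    puncta_multiplier: float = 0.6        # HSD puncta vs NF (1 = null)
    # tables
    tag_replicates: int = 9
    tag_fed_mean: float = 20.0            # µg/fly
    tag_stv_fraction: float = 0.5         # starved mean as fraction of fed
    tag_sd: float = 2.0
    lipid_replicates: int = 10
    qpcr_treatment_dct_shift: float = -8.0  # cycles vs control (fold 2^8)
    survival_n: int = 90
    survival_hazard_ratio: float = 3.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_s"] = list(d["window_s"])
        return d


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_foxo(cfg: RunConfig, seed: int) -> dict:
    seg_cfg = fqfoxo.SegmentationConfig(threshold_method=cfg.threshold_method,
                                        rim_fraction=cfg.rim_fraction)
    group_means = {}
    seeds = _spawn_seeds(seed, 2)
    for diet, s in zip(("NF", "HSD"), seeds):
        mult = 1.0 if diet == "NF" else cfg.foxo_multiplier
        spec = fqsynth.NucleiSceneSpec(
            n_nuclei=cfg.nuclei_per_group,
            image_shape=(32, 256, 256),
            nuclear_foxo=cfg.nuclear_foxo_nf * mult,
            noise_sd=cfg.foxo_noise_sd,
            seed=s,
        )
        lamin, foxo_stack, _ = fqsynth.generate_nuclei_stack(spec)
        labels, _, t = fqfoxo.segment_nuclei_2d(lamin, seg_cfg)
        masks = fqfoxo.reconstruct_nuclei_3d(lamin, labels, seg_cfg, threshold=t)
        meas = fqfoxo.measure_nuclear_intensity(foxo_stack, masks)
        group_means[diet] = [m.mean_intensity for m in meas]
    res = fqstats.wilcoxon_rank_sum(group_means["HSD"], group_means["NF"])
    return {
        "n_nuclei": {k: len(v) for k, v in group_means.items()},
        "mean_intensity": {k: float(np.mean(v)) for k, v in group_means.items()},
        "wilcoxon_p": res.p_value,
        "significant": bool(res.p_value < cfg.alpha),
    }


def _stage_flic(cfg: RunConfig, seed: int) -> dict:
    summaries = []
    cells = [(d, st) for d in ("NF", "HSD") for st in ("fed", "stv")]
    seeds = _spawn_seeds(seed, len(cells) * cfg.flies_per_cell)
    i = 0
    for diet, state in cells:
        rate = cfg.fed_bout_rate * (cfg.stv_feeding_multiplier if state == "stv" else 1.0)
        for fly in range(cfg.flies_per_cell):
            spec = fqsynth.FlicSceneSpec(
                duration=cfg.flic_duration_s,
                sampling_rate=cfg.flic_sampling_rate,
                bout_rate=rate, seed=seeds[i],
                threshold=cfg.flic_threshold,
            )
            series, _ = fqsynth.generate_flic_series(
                spec, well=f"{diet}-{state}-{fly}", diet=diet, state=state)
            events = fqflic.detect_events(series, threshold=cfg.flic_threshold,
                                          mode=cfg.event_mode)
            summaries.append(fqflic.summarize_window(events, series,
                                                     window=cfg.window_s))
            i += 1
    hdf = fqflic.hdf_contrast(summaries, between="diet", alpha=cfg.alpha,
                              ss_type=cfg.anova_ss_type)
    return {
        "cell_means": {f"{k[0]}|{k[1]}": v["mean"]
                       for k, v in hdf.anova.cell_stats.items()},
        "anova_p": {k: v.p_value for k, v in hdf.anova.effects.items()},
        "contrasts": hdf.contrasts.to_dict(orient="records"),
        "hdf_levels": hdf.hdf_levels,
    }


def _stage_puncta(cfg: RunConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    counts = {}
    for diet in ("NF", "HSD"):
        mult = 1.0 if diet == "NF" else cfg.puncta_multiplier
        per_fly = []
        for _ in range(cfg.flies_per_puncta_group):
            n_true = int(rng.poisson(cfg.nf_mean_puncta * mult))
            spec = fqsynth.PunctaSceneSpec(
                n_puncta=n_true, seed=int(rng.integers(2 ** 31)))
            stack, roi, _ = fqsynth.generate_puncta_scene(spec)
            res = fqpuncta.quantify_puncta(
                stack, roi, fqpuncta.PunctaConfig(min_size_px=4))
            per_fly.append(res.n_puncta)
        counts[diet] = per_fly
    res = fqpuncta.compare_groups_welch(counts["NF"], counts["HSD"])
    return {
        "mean_puncta": {k: float(np.mean(v)) for k, v in counts.items()},
        "welch_t": res.statistic, "welch_p": res.p_value,
        "significant": bool(res.p_value < cfg.alpha),
    }


def _stage_tables(cfg: RunConfig, seed: int) -> dict:
    seeds = _spawn_seeds(seed, 4)
    rng = np.random.default_rng(seeds[0])
    # TAG: fed vs starved within one diet/day
    fed = [fqtables.TagRecord(f"r{i}", 3,
                              3 * max(rng.normal(cfg.tag_fed_mean, cfg.tag_sd), 0.0))
           for i in range(cfg.tag_replicates)]
    stv = [fqtables.TagRecord(
        f"r{i}", 3,
        3 * max(rng.normal(cfg.tag_fed_mean * cfg.tag_stv_fraction, cfg.tag_sd), 0.0),
        state="stv") for i in range(cfg.tag_replicates)]
    d_tag, normalized = fqtables.delta_tag(fed, stv)

    # lipid classes: PE up, LPE down under HSD
    rng2 = np.random.default_rng(seeds[1])
    rows = []
    base = {"PE": 30.0, "PC": 40.0, "LPE": 5.0, "LPC": 6.0}
    shift = {"PE": 1.3, "PC": 1.1, "LPE": 0.6, "LPC": 0.9}
    for cls, mu in base.items():
        for diet in ("NF", "HSD"):
            m = mu * (shift[cls] if diet == "HSD" else 1.0)
            for rep in range(cfg.lipid_replicates):
                for tail in ("34.1", "36.2"):
                    rows.append({"species": f"{cls} {tail}", "class": cls,
                                 "replicate": f"{diet}-{rep}", "diet": diet,
                                 "day": 14,
                                 "concentration": max(rng2.normal(m / 2, m / 20), 0.0)})
    classes = fqtables.aggregate_lipid_classes(pd.DataFrame(rows))
    lipid = fqtables.compare_lipid_classes(classes, design="welch")

    # qPCR fold change
    rng3 = np.random.default_rng(seeds[2])
    qrows = []
    for grp, shift_ct in (("control", 0.0), ("treatment", cfg.qpcr_treatment_dct_shift)):
        for i in range(3):
            ref = rng3.normal(18.0, 0.2)
            qrows.append({"sample": f"{grp}-{i}", "group": grp,
                          "ct_target": ref + 6.0 + shift_ct + rng3.normal(0, 0.1),
                          "ct_reference": ref})
    folds = fqtables.ddct_fold_change(pd.DataFrame(qrows))
    treat_fold = float(folds.loc[folds["group"] == "treatment", "fold_change"].mean())

    # survival: exponential with a hazard ratio between diets
    rng4 = np.random.default_rng(seeds[3])
    t1 = rng4.exponential(10.0, cfg.survival_n)
    t2 = rng4.exponential(10.0 / cfg.survival_hazard_ratio, cfg.survival_n)
    surv = fqstats.mantel_cox(np.concatenate([t1, t2]),
                              ["NF"] * cfg.survival_n + ["HSD"] * cfg.survival_n)
    return {
        "delta_tag_ug_per_fly": d_tag,
        "tag_normalized_to_fed": normalized,
        "lipid_welch_p_adj": {cls: r.p_adjusted for cls, r in lipid.items()},
        "qpcr_treatment_mean_fold": treat_fold,
        "logrank_chi2": surv.statistic, "logrank_p": surv.p_value,
    }


def run_end_to_end(cfg: RunConfig, out_dir=None) -> dict:
    """Execute every stage and return (and optionally write) the report."""
    stage_seeds = _spawn_seeds(cfg.seed, 4)
    report = {"schema_version": REPORT_SCHEMA_VERSION, "config": cfg.to_dict()}
    for name, fn, s in [
        ("nuclear_foxo", _stage_foxo, stage_seeds[0]),
        ("flic_feeding", _stage_flic, stage_seeds[1]),
        ("apoii_puncta", _stage_puncta, stage_seeds[2]),
        ("metabolic_tables", _stage_tables, stage_seeds[3]),
    ]:
        try:
            report[name] = fn(cfg, s)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed on its input: {exc}") from exc
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        (out_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
    return report
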