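"""Method-comparison statistics and the multi-case study orchestrator.

Implements the statistical layer of the hotspot comparison: per-case
consensus (mean of the two observers), Spearman correlation, Bland–Altman
analysis with listing of cases beyond 1.96 SD of the mean difference,
paired t-tests, and six-number distribution summaries (mean, min, Q1,
median, Q3, max). ``run_study`` drives the full pipeline over many
synthetic cases: both masking arms, the automated hotspot search and two
simulated observers, with VDS-failed cases excluded pairwise from the VDS
comparisons only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import masking, observer, simgen
from .cells import DetectionParams, detect_nuclei
from .errors import NoHotspotError
from .hotspot import Hotspot, SearchParams, find_hotspot
from .observer import ObserverProfile, score_manual

__all__ = ["PairedScores", "AgreementReport", "StudyConfig", "StudyReport",
           "consensus_mean", "spearman_r", "bland_altman", "paired_t",
           "summarize_distribution", "run_study"]


@dataclass
class PairedScores:
    """Per-case PI pairs for two scoring methods (complete cases only)."""

    case_ids: list
    a: np.ndarray
    b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if len(self.a) != len(self.b) or len(self.a) != len(self.case_ids):
            raise ValueError("paired scores must align")
        if len(self.a) < 3:
            raise ValueError("need at least 3 paired scores")
        for arr in (self.a, self.b):
            if np.any(~np.isfinite(arr)) or arr.min() < 0 or arr.max() > 100:
                raise ValueError("scores must be finite percentages in [0, 100]")


def consensus_mean(obs1, obs2) -> np.ndarray:
    """Element-wise mean of the two observers' scores."""
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return (a + b) / 2.0


def spearman_r(a, b) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; NaN if degenerate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors, n >= 3")
    if np.ptp(sps.rankdata(a)) == 0 or np.ptp(sps.rankdata(b)) == 0:
        return float("nan")
    return float(sps.spearmanr(a, b).statistic)


def paired_t(a, b) -> tuple[float, float]:
    """Paired two-sided t-test; infinite t (p=0) for constant non-zero
    differences, t=0 (p=1) for identical vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length vectors, n >= 2")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean)) * float("inf"), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class AgreementReport:
    """Spearman + Bland–Altman + paired-t summary for one method pair."""

    label_a: str
    label_b: str
    n: int
    spearman: float
    pearson: float
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    outside_cases: list
    outside_fraction: float
    t_statistic: float
    t_pvalue: float
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("label_a", "label_b", "n", "spearman", "pearson",
                 "mean_difference", "sd_difference", "loa_low", "loa_high",
                 "outside_cases", "outside_fraction", "t_statistic", "t_pvalue")}


def bland_altman(pairs: PairedScores) -> AgreementReport:
    """Bland–Altman agreement of method A against method B.

    Differences d = A − B; SD uses the n−1 denominator; limits of agreement
    are mean ± 1.96·SD; cases with |d − mean| strictly greater than 1.96·SD
    are listed as outside.
    """
    d = pairs.a - pairs.b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (mean - 1.96 * sd, mean + 1.96 * sd)
    outside = np.abs(d - mean) > 1.96 * sd
    out_ids = [cid for cid, flag in zip(pairs.case_ids, outside) if flag]
    t, p = paired_t(pairs.a, pairs.b)
    pearson = float(np.corrcoef(pairs.a, pairs.b)[0, 1]) \
        if np.ptp(pairs.a) > 0 and np.ptp(pairs.b) > 0 else float("nan")
    return AgreementReport(
        pairs.label_a, pairs.label_b, len(d),
        spearman_r(pairs.a, pairs.b), pearson,
        mean, sd, loa[0], loa[1], out_ids, len(out_ids) / len(d), t, p,
        means=(pairs.a + pairs.b) / 2.0, differences=d)


def summarize_distribution(scores) -> dict:
    """Mean, min, Q1, median, Q3, max (quartiles by linear interpolation)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return {"mean": float(arr.mean()), "min": float(arr.min()), "q1": float(q1),
            "median": float(q2), "q3": float(q3), "max": float(arr.max())}


def simulate_bland_altman_coverage(n: int, reps: int,
                                   rng: np.random.Generator) -> float:
    """Long-run fraction of cases outside the 1.96 SD band.

    Draws ``reps`` cohorts of ``n`` normal between-method differences,
    flags cases with |d − mean| > 1.96·SD (sample mean/SD, n−1), and
    returns the mean outside fraction. Under normality this sits near
    0.05, the value the limits of agreement are built to approximate.
    """
    d = rng.standard_normal((reps, n))
    mean = d.mean(axis=1, keepdims=True)
    sd = d.std(axis=1, ddof=1, keepdims=True)
    outside = np.abs(d - mean) > 1.96 * sd
    return float(outside.mean())


# ---------------------------------------------------------------------------
# Study orchestration


@dataclass
class StudyConfig:
    """Conditions of a simulated multi-case comparison study.

    ``non_serial_fraction`` controls how many cases get a corrupted CK
    section (the misalignment failure pathway); the first
    ``round(fraction * n)`` cases are corrupted. ``detection_source``
    chooses whether the DIA arms score detector output on rendered images
    ("image") or the ground-truth cell table ("ground_truth"); the VDS
    registration step always runs on rendered sections when the vds arm is
    requested.
    """

    n_cases: int = 20
    seed: int = 0
    spec_overrides: dict = field(default_factory=dict)
    vary_positivity: bool = True
    non_serial_fraction: float = 0.27
    arms: tuple[str, ...] = ("vds", "rule", "manual")
    detection_source: str = "ground_truth"
    search_params: SearchParams = field(default_factory=SearchParams)
    detection_params: DetectionParams = field(default_factory=DetectionParams)
    observer_profiles: tuple[ObserverProfile, ...] = (
        ObserverProfile(observer_id=1, seed=101),
        ObserverProfile(observer_id=2, seed=202),
    )
    vds_failure_threshold: float = masking.DEFAULT_FAILURE_THRESHOLD

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "search_params" in kwargs:
            kwargs["search_params"] = SearchParams(**kwargs["search_params"])
        if "detection_params" in kwargs:
            kwargs["detection_params"] = DetectionParams(**kwargs["detection_params"])
        if "observer_profiles" in kwargs:
            kwargs["observer_profiles"] = tuple(
                ObserverProfile(**p) for p in kwargs["observer_profiles"])
        if "arms" in kwargs:
            kwargs["arms"] = tuple(kwargs["arms"])
        return cls(**kwargs)


@dataclass
class StudyReport:
    """All per-case scores, per-arm summaries and pairwise agreement."""

    scores: pd.DataFrame            # case_id, arm, pi_percent, n_cells
    summaries: dict                  # arm -> six-number summary
    agreements: dict                 # "a_vs_b" -> AgreementReport
    vds_excluded: list
    unscorable: list
    config: StudyConfig

    def pair(self, key: str) -> AgreementReport:
        return self.agreements[key]

    def arm_scores(self, arm: str) -> pd.Series:
        sub = self.scores[self.scores["arm"] == arm]
        return sub.set_index("case_id")["pi_percent"]

    def to_json(self, path) -> None:
        payload = {
            "summaries": self.summaries,
            "agreements": {k: v.as_dict() for k, v in self.agreements.items()},
            "vds_excluded": self.vds_excluded,
            "unscorable": self.unscorable,
            "n_cases": int(self.config.n_cases),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def write_scores_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)

    def write_plots(self, directory) -> list[Path]:
        """Scatter + Bland–Altman PNGs per method pair (artifacts only)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for key, rep in self.agreements.items():
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
            a = rep.means + rep.differences / 2
            b = rep.means - rep.differences / 2
            ax1.scatter(b, a, s=12, alpha=0.7)
            lim = max(100.0, a.max(), b.max())
            ax1.plot([0, lim], [0, lim], "k--", lw=0.8)
            ax1.set_xlabel(f"{rep.label_b} Ki67 PI (%)")
            ax1.set_ylabel(f"{rep.label_a} Ki67 PI (%)")
            ax1.set_title(f"r = {rep.spearman:.2f}")
            ax2.scatter(rep.means, rep.differences, s=12, alpha=0.7)
            for yv, style in ((rep.mean_difference, "-"),
                              (rep.loa_low, "--"), (rep.loa_high, "--")):
                ax2.axhline(yv, color="k", ls=style, lw=0.8)
            ax2.set_xlabel("mean of methods (%)")
            ax2.set_ylabel(f"{rep.label_a} − {rep.label_b} (%)")
            fig.tight_layout()
            out = directory / f"{key}.png"
            fig.savefig(out, dpi=120)
            plt.close(fig)
            written.append(out)
        return written


def _case_spec(config: StudyConfig, index: int) -> simgen.SlideSpec:
    ss = np.random.SeedSequence([config.seed, index])
    seed = int(ss.generate_state(1)[0] % (2 ** 31))
    overrides = dict(config.spec_overrides)
    n_non = int(round(config.non_serial_fraction * config.n_cases))
    overrides["serial_mode"] = "non_serial" if index < n_non else "serial"
    overrides["seed"] = seed
    if config.vary_positivity and not {"baseline_positivity",
                                       "hotspot_peak_positivity"} & set(overrides):
        # cohort heterogeneity: per-case hotspot contrast spanning the
        # clinical range of Ki67 PIs (~1%..90%+)
        rng = np.random.default_rng(ss.spawn(1)[0])
        peak = float(rng.uniform(0.05, 0.95))
        overrides["hotspot_peak_positivity"] = peak
        overrides["baseline_positivity"] = peak * float(rng.uniform(0.2, 0.6))
    return simgen.SlideSpec(**overrides)


def _dia_cells(case: simgen.SyntheticCase, config: StudyConfig) -> pd.DataFrame:
    if config.detection_source == "image":
        table = detect_nuclei(case.ki67_image, case.resolution_um_per_px,
                              config.detection_params)
        return table.df
    return case.cells


def run_study(config: StudyConfig) -> StudyReport:
    """Run every requested arm on every case and assemble the report.

    VDS-failed cases are excluded from VDS pairs only; a case failing all
    requested arms is listed as unscorable, never silently dropped.
    """
    need_images = "vds" in config.arms or config.detection_source == "image"
    rows = []
    vds_excluded: list = []
    unscorable: list = []

    for i in range(config.n_cases):
        spec = _case_spec(config, i)
        case = simgen.generate_case(spec, render=need_images)
        case_id = f"case_{i:03d}"
        extent = (spec.width_um, spec.height_um)
        scored_any = False
        dia = _dia_cells(case, config)

        if "rule" in config.arms:
            mask = masking.build_mask_rule(spec.shape_px, regions=case.regions,
                                           resolution_um_per_px=spec.resolution_um_per_px)
            kept = masking.filter_cells_by_mask(dia, mask)
            try:
                hs = find_hotspot(kept, params=config.search_params,
                                  extent_um=extent, method="rule")
                rows.append((case_id, "rule", hs.pi_percent, hs.n_cells))
                scored_any = True
            except NoHotspotError:
                pass

        if "vds" in config.arms:
            reg = masking.register_serial(
                case.ck_image, case.ki67_image, spec.resolution_um_per_px,
                failure_threshold=config.vds_failure_threshold)
            if reg.status != "success":
                vds_excluded.append(case_id)
            else:
                exclusions = [r for r in case.regions
                              if r.region_class in ("benign_epithelium",
                                                    "carcinoma_in_situ")]
                mask = masking.build_mask_vds(case.ck_image, reg, exclusions,
                                              spec.resolution_um_per_px)
                kept = masking.filter_cells_by_mask(dia, mask)
                try:
                    hs = find_hotspot(kept, params=config.search_params,
                                      extent_um=extent, method="vds")
                    rows.append((case_id, "vds", hs.pi_percent, hs.n_cells))
                    scored_any = True
                except NoHotspotError:
                    pass

        if "manual" in config.arms:
            for profile in config.observer_profiles:
                score = score_manual(case, profile)
                rows.append((case_id, f"observer{profile.observer_id}",
                             score.pi_percent, score.n_counted))
                scored_any = True

        if not scored_any:
            unscorable.append(case_id)

    scores = pd.DataFrame(rows, columns=["case_id", "arm", "pi_percent", "n_cells"])

    if "manual" in config.arms and len(config.observer_profiles) >= 2:
        o1 = scores[scores["arm"] == "observer1"].set_index("case_id")
        o2 = scores[scores["arm"] == "observer2"].set_index("case_id")
        common = o1.index.intersection(o2.index)
        cons = consensus_mean(o1.loc[common, "pi_percent"],
                              o2.loc[common, "pi_percent"])
        scores = pd.concat([scores, pd.DataFrame({
            "case_id": common, "arm": "consensus", "pi_percent": cons,
            "n_cells": (o1.loc[common, "n_cells"].to_numpy()
                        + o2.loc[common, "n_cells"].to_numpy()) / 2,
        })], ignore_index=True)

    summaries = {arm: summarize_distribution(sub["pi_percent"])
                 for arm, sub in scores.groupby("arm") if len(sub)}

    agreements = {}
    pairs = [("consensus", "vds"), ("consensus", "rule"), ("observer1", "observer2")]
    for la, lb in pairs:
        sa = scores[scores["arm"] == la].set_index("case_id")["pi_percent"]
        sb = scores[scores["arm"] == lb].set_index("case_id")["pi_percent"]
        common = sa.index.intersection(sb.index)
        if len(common) >= 3:
            agreements[f"{la}_vs_{lb}"] = bland_altman(PairedScores(
                list(common), sa.loc[common].to_numpy(), sb.loc[common].to_numpy(),
                la, lb))

    return StudyReport(scores, summaries, agreements, vds_excluded, unscorable, config)
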