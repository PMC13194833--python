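"""End-to-end orchestration: simulate -> preprocess -> connect -> network ->
metrics -> reliability -> group statistics.

`run_pipeline` executes the whole analysis for every configured
(measure x cleaning) combination from a single :class:`RunConfig` and a
single seed, and returns the epoch-level index table, the ICC reliability
grid, the screened LME table (with pooled FDR correction and Cohen's f²)
and the psychometric correlation table.  All randomness derives from
``cfg.seed``; reruns with the same config are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (ArtifactSpec, Cohort, GroundTruthSpec, GroupEffect,
                     default_template, generate_cohort)
from .connectivity import (BANDS, cross_spectrum, default_freq_grid, dtf,
                           fit_mvar, icoh, transfer_matrix, wpli)
from .network import threshold
from .metrics import compute_indices
from .preprocessing import (ASRCleaner, FilterChain, ICACleaner, Epoch,
                            epoch_recording, power_ratio)
from . import stats as rstats


@dataclass
class RunConfig:
    """Single source of truth for one pipeline run.

    Defaults are the emulated study conditions: 2 x 19 subjects, two states,
    20 channels at 500 Hz, 40 six-second epochs after a 10-s discard, all
    three estimators under both cleaners, 15% network density, ICC >= 0.60
    screening and FDR at 0.05.
    """

    seed: int = 0
    n_per_group: int = 19
    states: tuple[str, ...] = ("EO", "EC")
    n_channels: int = 20
    duration_s: float = 250.0
    fs: float = 500.0
    discard_s: float = 10.0
    epoch_s: float = 6.0
    analysis_s: float = 240.0
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma", "full")
    measures: tuple[str, ...] = ("DTF", "iCOH", "wPLI")
    cleanings: tuple[str, ...] = ("ASR", "ICA")
    density: float = 0.15
    icc_threshold: float = 0.60
    fdr_alpha: float = 0.05
    p_min: int = 1
    p_max: int = 30
    seg_s: float = 1.0
    seg_overlap: float = 0.5
    wpli_debias: bool = False
    asr: dict = field(default_factory=lambda: {
        "cutoff": 5.0, "window_s": 0.5, "overlap": 0.5, "maxdims": 0.66,
        "mode": "multichannel"})
    ica: dict = field(default_factory=lambda: {
        "kurtosis_thresh": 1.25, "amp_thresh_sd": 4.0})
    artifacts: dict = field(default_factory=lambda: {
        "line_amp": 5.0, "blink_rate": 0.2, "blink_amp": 80.0,
        "emg_rate": 0.1, "emg_amp": 20.0})
    group_effect: dict = field(default_factory=lambda: {
        "edge_removal_fraction": 0.5, "scope": "intra_module",
        "mode": "disperse"})
    coupling_jitter: float = 0.2
    subject_rewire_fraction: float = 0.2
    recall_coupling_r: float = -0.6
    modularity_restarts: int = 20
    #: seed of the group template (the emulated population); kept separate
    #: from `seed`, which governs the sampled cohort realization
    template_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("states", "bands", "measures", "cleanings"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def template(self) -> GroundTruthSpec:
        spec = default_template(
            n_channels=self.n_channels,
            artifact_spec=ArtifactSpec(**self.artifacts),
            group_effect=GroupEffect(**self.group_effect),
            seed=self.template_seed,
        )
        # the cohort realization (subjects, innovations, artifacts) follows
        # the run seed; the population template stays fixed
        return dataclasses.replace(spec, seed=self.seed)

    def cohort(self) -> Cohort:
        return generate_cohort(
            self.template(), n_per_group=self.n_per_group,
            states=tuple(self.states), duration_s=self.duration_s, fs=self.fs,
            coupling_jitter=self.coupling_jitter,
            subject_rewire_fraction=self.subject_rewire_fraction,
            recall_coupling_r=self.recall_coupling_r,
            effect_seed=self.template_seed)


@dataclass
class PipelineResult:
    long_table: pd.DataFrame         # epoch-level graph indices
    reliability: pd.DataFrame        # ICC grid
    screened: pd.DataFrame           # cells passing the ICC screen
    lme: pd.DataFrame                # group-inference table (Table-4 style)
    correlations: pd.DataFrame       # psychometric correlations (Table-5 style)
    power_ratios: pd.DataFrame       # per epoch x channel clean/raw ratios
    psychometrics: pd.DataFrame
    manifest: pd.DataFrame
    run_info: dict | None = None     # config + config hash for provenance

    def write(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.long_table.to_csv(out / "indices_long.csv", index=False)
        self.reliability.to_csv(out / "reliability.csv", index=False)
        self.screened.to_csv(out / "screened.csv", index=False)
        self.lme.to_csv(out / "lme.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.power_ratios.to_csv(out / "power_ratios.csv", index=False)
        self.psychometrics.to_csv(out / "psychometrics.csv", index=False)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        if self.run_info is not None:
            with open(out / "run_info.json", "w") as fh:
                json.dump(self.run_info, fh, indent=2)


def _make_cleaner(cleaning: str, cfg: RunConfig, rec_index: int):
    if cleaning == "ASR":
        return ASRCleaner(**cfg.asr)
    if cleaning == "ICA":
        return ICACleaner(seed=cfg.seed + 1009 * (rec_index + 1), **cfg.ica)
    raise ValueError(f"unknown cleaning '{cleaning}'")


def connectivity_for_epoch(ep: Epoch, cfg: RunConfig) -> dict[tuple[str, str], np.ndarray]:
    """All configured (measure, band) weight matrices of one broadband epoch."""
    out: dict[tuple[str, str], np.ndarray] = {}
    want_spectral = any(m in cfg.measures for m in ("iCOH", "wPLI"))
    if "DTF" in cfg.measures:
        model = fit_mvar(ep, cfg.p_min, cfg.p_max)
        H = transfer_matrix(model, default_freq_grid(), ep.fs)
        for b in cfg.bands:
            out[("DTF", b)] = dtf(H, BANDS[b], epoch_index=ep.index).W
    if want_spectral:
        S, segs = cross_spectrum(ep, seg_s=cfg.seg_s, overlap=cfg.seg_overlap,
                                 return_segments=True)
        for b in cfg.bands:
            if "iCOH" in cfg.measures:
                out[("iCOH", b)] = icoh(S, BANDS[b], epoch_index=ep.index).W
            if "wPLI" in cfg.measures:
                out[("wPLI", b)] = wpli(segs, BANDS[b], epoch_index=ep.index,
                                        debias=cfg.wpli_debias).W
    return out


def run_pipeline(cfg: RunConfig, out_dir=None) -> PipelineResult:
    """Execute all stages for every (measure x cleaning) combination."""
    from .connectivity import ConnectivityMatrix

    cohort = cfg.cohort()
    chain = FilterChain("full")
    index_rows: list[dict] = []
    ratio_rows: list[dict] = []

    for ri, rec in enumerate(cohort.recordings):
        raw_epochs = epoch_recording(rec, cfg.discard_s, cfg.epoch_s,
                                     cfg.analysis_s)
        filtered = chain.transform(raw_epochs)
        for cleaning in cfg.cleanings:
            cleaner = _make_cleaner(cleaning, cfg, ri)
            cleaned = cleaner.transform(filtered)
            for ep_clean, ep_raw in zip(cleaned, raw_epochs):
                ratios = power_ratio(ep_clean, ep_raw)
                ratio_rows.append({
                    "subject_id": rec.subject_id, "group": rec.group,
                    "state": rec.state, "cleaning": cleaning,
                    "epoch": ep_raw.index,
                    "mean_ratio": float(np.nanmean(ratios)),
                    **{f"ch{c}": float(r) for c, r in enumerate(ratios)},
                })
                conn = connectivity_for_epoch(ep_clean, cfg)
                for (measure, band), W in conn.items():
                    cm = ConnectivityMatrix(W, measure == "DTF", measure,
                                            band, ep_raw.index)
                    net = threshold(cm, cfg.density)
                    idx = compute_indices(net, seed=cfg.seed,
                                          n_restarts=cfg.modularity_restarts)
                    for name, value in idx.as_dict().items():
                        index_rows.append({
                            "subject_id": rec.subject_id, "group": rec.group,
                            "state": rec.state, "cleaning": cleaning,
                            "measure": measure, "band": band,
                            "epoch": ep_raw.index, "index_name": name,
                            "value": value,
                        })

    long_table = pd.DataFrame(index_rows)
    reliability = rstats.reliability_grid(long_table)
    screened = rstats.screen_reliability(reliability, cfg.icc_threshold)
    lme = rstats.lme_table(long_table, screened)
    correlations = _psychometric_correlations(long_table, cohort.psychometrics,
                                              reliability, cfg)
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    result = PipelineResult(long_table, reliability, screened, lme,
                            correlations, pd.DataFrame(ratio_rows),
                            cohort.psychometrics, cohort.manifest,
                            run_info={"config": cfg_dict,
                                      "config_hash": cfg_hash})
    if out_dir is not None:
        result.write(out_dir)
    return result


def primary_combination(reliability: pd.DataFrame) -> tuple[str, str]:
    """(measure, cleaning) with the highest mean ICC across all cells."""
    mean_icc = (reliability.groupby(["measure", "cleaning"])["icc"]
                .mean().sort_values(ascending=False))
    return mean_icc.index[0]


def _psychometric_correlations(long_table: pd.DataFrame, psych: pd.DataFrame,
                               reliability: pd.DataFrame,
                               cfg: RunConfig) -> pd.DataFrame:
    """Per-group correlations of epoch-mean indices (most reliable combo)."""
    measure, cleaning = primary_combination(reliability)
    state = "EC" if "EC" in cfg.states else cfg.states[-1]
    sub = long_table.query(
        "measure == @measure and cleaning == @cleaning and state == @state")
    score_cols = [c for c in ("TMT_A", "TMT_B", "immediate_memory", "recall")
                  if c in psych.columns]
    frames = []
    for group, gsub in sub.groupby("group"):
        means = (gsub.groupby(["subject_id", "band", "index_name"])["value"]
                 .mean().reset_index())
        means["col"] = means["band"] + "_" + means["index_name"]
        wide = means.pivot(index="subject_id", columns="col", values="value")
        scores = psych[psych["group"] == group].set_index("subject_id")[score_cols]
        if len(wide.index.intersection(scores.index)) < 4:
            continue  # too few subjects for a meaningful correlation table
        tab = rstats.correlate_with_psychometrics(wide, scores,
                                                  alpha=cfg.fdr_alpha)
        tab.insert(0, "group", group)
        tab.insert(1, "measure", measure)
        tab.insert(2, "cleaning", cleaning)
        tab.insert(3, "state", state)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["group", "measure", "cleaning", "state",
                                     "index_name", "score", "r", "p", "p_fdr",
                                     "significant"])
    return pd.concat(frames, ignore_index=True)


def compare_cleaning(cfg: RunConfig) -> pd.DataFrame:
    """Grand-averaged power-ratio summaries per (cleaning, state).

    Mirrors the preprocessed/raw power-ratio comparison: for every cleaner
    and state the distribution over subjects x channels x epochs of the
    clean/raw power ratio is summarized by its quartiles.
    """
    cohort = cfg.cohort()
    chain = FilterChain("full")
    rows = []
    for ri, rec in enumerate(cohort.recordings):
        raw_epochs = epoch_recording(rec, cfg.discard_s, cfg.epoch_s,
                                     cfg.analysis_s)
        filtered = chain.transform(raw_epochs)
        for cleaning in cfg.cleanings:
            cleaner = _make_cleaner(cleaning, cfg, ri)
            cleaned = cleaner.transform(filtered)
            for ep_clean, ep_raw in zip(cleaned, raw_epochs):
                for r in power_ratio(ep_clean, ep_raw):
                    rows.append({"cleaning": cleaning, "state": rec.state,
                                 "group": rec.group, "ratio": float(r)})
    df = pd.DataFrame(rows)
    summary = (df.groupby(["cleaning", "state"])["ratio"]
               .describe(percentiles=[0.25, 0.5, 0.75])
               .reset_index()
               .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"}))
    summary["iqr"] = summary["q3"] - summary["q1"]
    return summary
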