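"""Synthetic resting-state EEG cohorts with known directed coupling.

The generative model is a stable multivariate autoregressive (MVAR) process
observed through an instantaneous (zero-lag) mixing matrix that stands in for
volume conduction.  This is exactly the model class the directed transfer
function assumes, so every downstream stage of the pipeline can be validated
by parameter recovery against an analytic ground truth.

A cohort emulates the study design this package targets: two groups
("Control", "Miners") of 19 male subjects each, 20 channels in the 10-20
montage, two resting states (eyes open / eyes closed), 500 Hz, and 250 s of
signal per state (10 s discarded + 40 non-overlapping 6-s epochs).  The
"Miners" group receives a configurable topology shift of the true coupling
graph (by default, dispersal of half of the within-module coupling edges to
cross-module pairs, which lowers the true network's clustering at unchanged
density), and a psychometric table is emitted whose recall score depends
negatively on each subject's true clustering level, so that the
correlation stage is testable by recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

#: 20-channel 10-20 montage used throughout.
MONTAGE_20 = [
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8", "C3", "C4", "Cz",
    "T7", "T8", "P3", "P4", "Pz", "P7", "P8", "O1", "O2", "Oz",
]

#: Relative blink projection strength per channel (frontal-weighted).
_BLINK_WEIGHTS = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.5, "F8": 0.5, "F3": 0.45, "F4": 0.45,
    "Fz": 0.4, "C3": 0.1, "C4": 0.1, "Cz": 0.1,
}


@dataclass
class Recording:
    """A continuous multichannel EEG recording (channels x samples, µV)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str
    group: str
    state: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be distinct")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class ArtifactSpec:
    """Rates (events/s) and amplitudes (µV) of injected artifacts."""

    line_amp: float = 0.0          # 50 Hz sinusoid amplitude, all channels
    blink_rate: float = 0.0        # Poisson rate of blink transients
    blink_amp: float = 0.0         # peak blink amplitude at Fp1/Fp2
    emg_rate: float = 0.0          # Poisson rate of broadband 60-100 Hz bursts
    emg_amp: float = 0.0           # burst RMS amplitude

    def validate(self) -> None:
        for name in ("line_amp", "blink_rate", "blink_amp", "emg_rate", "emg_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def any_active(self) -> bool:
        return any(
            getattr(self, n) > 0
            for n in ("line_amp", "blink_rate", "emg_rate")
        )


@dataclass
class GroupEffect:
    """Topology shift applied to the 'Miners' group template.

    ``mode="disperse"`` (default) relocates a fraction of the within-module
    coupling edges to absent cross-module pairs, preserving the edge count
    while breaking triangles — the true network becomes less clustered/
    segregated at unchanged density.  ``mode="remove"`` deletes a fraction
    of the edges in ``scope`` instead, lowering the true edge density.
    """

    edge_removal_fraction: float = 0.5
    scope: str = "intra_module"  # intra_module | cross_module | any
    mode: str = "disperse"       # disperse | remove


@dataclass
class GroundTruthSpec:
    """Ground truth for one subject (or a group template).

    ``coupling`` holds the non-zero MVAR coefficients as
    ``(source, target, coeffs)`` entries, one coefficient per lag; the implied
    lag matrices ``A_k`` satisfy ``x_t = sum_k A_k x_{t-k} + e_t`` with
    ``A_k[target, source] = coeffs[k-1]``.
    """

    n_channels: int = 20
    mvar_order: int = 2
    coupling: list[tuple[int, int, tuple[float, ...]]] = field(default_factory=list)
    noise_cov: np.ndarray | None = None
    mixing: np.ndarray | None = None
    modules: np.ndarray | None = None
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    group_effect: GroupEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_channels
        if self.noise_cov is None:
            self.noise_cov = np.eye(n)
        if self.mixing is None:
            self.mixing = np.eye(n)
        if self.modules is None:
            self.modules = np.repeat(np.arange(2), [n - n // 2, n // 2])
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.modules = np.asarray(self.modules)

    # ---- derived quantities -------------------------------------------------

    def coefficient_array(self) -> np.ndarray:
        """Stack of lag matrices, shape ``(p, n, n)``."""
        A = np.zeros((self.mvar_order, self.n_channels, self.n_channels))
        for src, dst, coeffs in self.coupling:
            for k, c in enumerate(coeffs):
                A[k, dst, src] = c
        return A

    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coefficient_array())

    @property
    def stable(self) -> bool:
        return self.spectral_radius() < 1.0

    def validate(self) -> None:
        if not self.stable:
            raise ValueError(
                "unstable MVAR specification: companion spectral radius "
                f"{self.spectral_radius():.4f} >= 1"
            )
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise_cov must be positive definite")
        if not np.allclose(np.diag(self.mixing), 1.0):
            raise ValueError("mixing must have unit diagonal")
        self.artifact_spec.validate()

    # ---- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("noise_cov", "mixing", "modules"):
            d[key] = np.asarray(d[key]).tolist()
        d["coupling"] = [[s, t, list(c)] for s, t, c in self.coupling]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthSpec":
        d = json.loads(text)
        d["coupling"] = [(s, t, tuple(c)) for s, t, c in d["coupling"]]
        for key in ("noise_cov", "mixing", "modules"):
            d[key] = np.asarray(d[key])
        d["artifact_spec"] = ArtifactSpec(**d["artifact_spec"])
        if d["group_effect"] is not None:
            d["group_effect"] = GroupEffect(**d["group_effect"])
        return cls(**d)


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of lag stack ``A`` (p, n, n)."""
    p, n, _ = A.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def default_template(
    n_channels: int = 20,
    mvar_order: int = 2,
    clique_size: int = 4,
    intra_module_prob: float = 0.05,
    cross_module_prob: float = 0.05,
    coupling_strength: float = 0.25,
    self_coeffs: tuple[float, ...] = (0.5, -0.15),
    mixing_strength: float = 0.2,
    artifact_spec: ArtifactSpec | None = None,
    group_effect: GroupEffect | None = None,
    seed: int = 0,
) -> GroundTruthSpec:
    """Build the group-template spec used as the study stand-in.

    Channels are split into two modules (anterior / posterior halves).  Each
    channel carries an oscillatory self-model.  Within every module the
    channels are partitioned into cliques of mutually (bidirectionally)
    coupled channels — the local, segregated circuits that give the healthy
    template its high directed clustering — with additional sparse random
    coupling within and across modules.  A distance-decaying zero-lag mixing
    matrix emulates volume conduction.  The coupling is scaled down, if
    needed, until the companion spectral radius is below 0.9.
    """
    rng = np.random.default_rng(seed)
    modules = np.repeat(np.arange(2), [n_channels - n_channels // 2, n_channels // 2])
    coupling: list[tuple[int, int, tuple[float, ...]]] = []
    seen: set[tuple[int, int]] = set()
    for i in range(n_channels):
        coeffs = tuple(self_coeffs) + (0.0,) * (mvar_order - len(self_coeffs))
        coupling.append((i, i, coeffs[:mvar_order]))

    def add_edge(src: int, dst: int) -> None:
        if (src, dst) in seen:
            return
        seen.add((src, dst))
        c = coupling_strength * rng.uniform(0.8, 1.2)
        coupling.append((src, dst, (c,) + (0.0,) * (mvar_order - 1)))

    # mutually coupled cliques inside each module
    for mod in np.unique(modules):
        members = np.where(modules == mod)[0]
        rng.shuffle(members)
        for start in range(0, len(members), clique_size):
            clique = members[start:start + clique_size]
            for a in clique:
                for b in clique:
                    if a != b:
                        add_edge(int(a), int(b))
    # sparse random background coupling
    for src in range(n_channels):
        for dst in range(n_channels):
            if src == dst:
                continue
            p_edge = (intra_module_prob if modules[src] == modules[dst]
                      else cross_module_prob)
            if rng.random() < p_edge:
                add_edge(src, dst)

    # volume-conduction surrogate: unit diagonal, decaying off-diagonal
    idx = np.arange(n_channels)
    dist = np.abs(idx[:, None] - idx[None, :])
    mixing = np.where(dist == 0, 1.0, mixing_strength * np.exp(-(dist - 1) / 2.0))

    spec = GroundTruthSpec(
        n_channels=n_channels,
        mvar_order=mvar_order,
        coupling=coupling,
        mixing=mixing,
        modules=modules,
        artifact_spec=artifact_spec or ArtifactSpec(),
        group_effect=group_effect,
        seed=seed,
    )
    return _stabilize(spec)


def _stabilize(spec: GroundTruthSpec, target_radius: float = 0.9) -> GroundTruthSpec:
    """Scale cross-channel couplings until the process is comfortably stable."""
    for _ in range(60):
        if spec.spectral_radius() <= target_radius:
            return spec
        coupling = [
            (s, t, c) if s == t else (s, t, tuple(0.9 * x for x in c))
            for s, t, c in spec.coupling
        ]
        spec = replace(spec, coupling=coupling)
    raise ValueError("failed to stabilize template coupling")


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def generate_mvar_recording(
    spec: GroundTruthSpec,
    duration_s: float,
    fs: float,
    rng: np.random.Generator | None = None,
    subject_id: str = "S00",
    group: str = "Control",
    state: str = "EC",
    burn_in: int = 1000,
    scale_uv: float = 10.0,
) -> Recording:
    """Realize the specified MVAR process, mixed by ``spec.mixing``.

    Deterministic given the generator state (``rng`` defaults to
    ``default_rng(spec.seed)``).  Raises on an unstable specification with an
    explicit spectral-radius report.
    """
    spec.validate()
    n_samples = duration_s * fs
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise ValueError("duration_s * fs must be an integer number of samples")
    n_samples = int(round(n_samples))
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    A = spec.coefficient_array()
    p, n, _ = A.shape
    chol = np.linalg.cholesky(spec.noise_cov)
    total = n_samples + burn_in
    e = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    for t in range(p, total):
        acc = e[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - k - 1]
        x[t] = acc
    data = (spec.mixing @ x[burn_in:].T) * scale_uv
    return Recording(data, fs, list(MONTAGE_20[:n]) if n <= 20 else
                     [f"ch{i}" for i in range(n)],
                     subject_id, group, state)


def inject_artifacts(
    rec: Recording,
    spec: GroundTruthSpec,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, dict]:
    """Add line noise, blinks and EMG bursts; returns a new recording + log.

    * 50 Hz sinusoid of amplitude ``line_amp`` on every channel,
    * frontal-weighted low-frequency blink transients (0.4 s raised-cosine
      squared kernel) at Poisson onsets,
    * broadband 60-100 Hz bursts (0.3 s Hann-enveloped band-passed noise) on a
      random channel neighborhood at Poisson onsets.

    With all rates/amplitudes zero the output equals the input.
    """
    art = spec.artifact_spec
    art.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    fs, n_samp = rec.fs, rec.data.shape[1]
    duration = n_samp / fs
    data = rec.data.copy()
    log: dict = {"line_amp": art.line_amp, "blink_times": [], "emg_times": []}

    if art.line_amp > 0:
        t = np.arange(n_samp) / fs
        data += art.line_amp * np.sin(2 * np.pi * 50.0 * t)[None, :]

    if art.blink_rate > 0 and art.blink_amp > 0:
        kernel_len = int(0.4 * fs)
        kernel = np.hanning(kernel_len) ** 2
        weights = np.array([_BLINK_WEIGHTS.get(lbl, 0.05) for lbl in rec.channel_labels])
        n_events = rng.poisson(art.blink_rate * duration)
        onsets = np.sort(rng.uniform(0, duration - 0.4, size=n_events))
        for onset in onsets:
            i0 = int(onset * fs)
            data[:, i0:i0 + kernel_len] += art.blink_amp * weights[:, None] * kernel[None, :]
            log["blink_times"].append(float(onset))

    if art.emg_rate > 0 and art.emg_amp > 0:
        burst_len = int(0.3 * fs)
        sos = sps.butter(4, [60.0, 100.0], btype="bandpass", fs=fs, output="sos")
        env = np.hanning(burst_len)
        n_events = rng.poisson(art.emg_rate * duration)
        onsets = np.sort(rng.uniform(0, duration - 0.3, size=n_events))
        for onset in onsets:
            i0 = int(onset * fs)
            center = rng.integers(rec.n_channels)
            ch_w = np.exp(-np.abs(np.arange(rec.n_channels) - center) / 2.0)
            noise = sps.sosfilt(sos, rng.standard_normal(burst_len))
            noise *= env / max(np.std(noise), 1e-12)
            data[:, i0:i0 + burst_len] += art.emg_amp * ch_w[:, None] * noise[None, :]
            log["emg_times"].append(float(onset))

    out = Recording(data, rec.fs, rec.channel_labels, rec.subject_id,
                    rec.group, rec.state)
    return out, log


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    recordings: list[Recording]
    subject_specs: dict[str, GroundTruthSpec]
    psychometrics: pd.DataFrame
    manifest: pd.DataFrame


#: Psychometric summaries (mean, sd) per group, used as generative anchors.
_PSYCH_ANCHORS = {
    "Control": {"TMT_A": (28.58, 5.92), "TMT_B": (62.63, 14.90),
                "immediate_memory": (7.16, 1.34), "recall": (13.26, 1.59)},
    "Miners": {"TMT_A": (34.78, 8.11), "TMT_B": (87.22, 28.63),
               "immediate_memory": (5.31, 1.60), "recall": (10.95, 2.01)},
}


def _apply_group_effect(
    spec: GroundTruthSpec, effect: GroupEffect, rng: np.random.Generator
) -> GroundTruthSpec:
    """Disperse or remove a fraction of coupling edges in the given scope."""
    modules = spec.modules
    cross = [(i, e) for i, e in enumerate(spec.coupling) if e[0] != e[1]]
    if effect.scope == "intra_module":
        pool = [i for i, e in cross if modules[e[0]] == modules[e[1]]]
    elif effect.scope == "cross_module":
        pool = [i for i, e in cross if modules[e[0]] != modules[e[1]]]
    else:
        pool = [i for i, _ in cross]
    n_hit = int(round(effect.edge_removal_fraction * len(pool)))
    if pool and effect.mode == "remove" and n_hit >= len(cross):
        raise ValueError("group effect would remove all cross-channel edges")
    hit = set(rng.choice(pool, size=n_hit, replace=False)) if n_hit else set()

    if effect.mode == "remove":
        coupling = [e for i, e in enumerate(spec.coupling) if i not in hit]
        return replace(spec, coupling=coupling)
    if effect.mode != "disperse":
        raise ValueError("group_effect mode must be 'disperse' or 'remove'")

    present = {(s, t) for s, t, _ in spec.coupling}
    absent_cross = [(s, t) for s in range(spec.n_channels)
                    for t in range(spec.n_channels)
                    if s != t and (s, t) not in present
                    and modules[s] != modules[t]]
    rng.shuffle(absent_cross)
    coupling = []
    ai = 0
    for i, (s, t, c) in enumerate(spec.coupling):
        if i in hit and ai < len(absent_cross):
            ns, nt = absent_cross[ai]
            ai += 1
            coupling.append((ns, nt, c))
        else:
            coupling.append((s, t, c))
    return replace(spec, coupling=coupling)


def _jitter_coupling(
    spec: GroundTruthSpec, rng: np.random.Generator, rel_sd: float
) -> GroundTruthSpec:
    coupling = [
        (s, t, tuple(c * (1.0 + rel_sd * rng.standard_normal()) for c in coeffs))
        for s, t, coeffs in spec.coupling
    ]
    return _stabilize(replace(spec, coupling=coupling), target_radius=0.95)


def _rewire_coupling(
    spec: GroundTruthSpec, rng: np.random.Generator, fraction: float
) -> GroundTruthSpec:
    """Individualize a subject's coupling topology.

    A fraction of the cross-channel edges is relocated to previously absent
    ordered pairs of the same type (within-module edges stay within a
    module, cross-module edges stay cross-module; coefficient magnitudes are
    reused).  Subjects thus share the group template's modular statistics
    but not an identical connectome — the source of genuine between-subject
    variance in topology-dependent indices.
    """
    if fraction <= 0:
        return spec
    modules = spec.modules
    cross_idx = [i for i, e in enumerate(spec.coupling) if e[0] != e[1]]
    n_move = int(round(fraction * len(cross_idx)))
    if n_move == 0:
        return spec
    move = set(rng.choice(cross_idx, size=n_move, replace=False))
    present = {(s, t) for s, t, _ in spec.coupling}
    absent = [(s, t) for s in range(spec.n_channels)
              for t in range(spec.n_channels)
              if s != t and (s, t) not in present]
    rng.shuffle(absent)
    intra_slots = [p for p in absent if modules[p[0]] == modules[p[1]]]
    cross_slots = [p for p in absent if modules[p[0]] != modules[p[1]]]
    coupling = []
    for i, (s, t, coeffs) in enumerate(spec.coupling):
        slots = intra_slots if modules[s] == modules[t] else cross_slots
        if i in move and slots:
            ns, nt = slots.pop()
            coupling.append((ns, nt, coeffs))
        else:
            coupling.append((s, t, coeffs))
    return replace(spec, coupling=coupling)


def true_clustering(spec: GroundTruthSpec) -> float:
    """Directed clustering coefficient of the subject's true coupling graph."""
    from .metrics import clustering

    A = np.zeros((spec.n_channels, spec.n_channels), dtype=int)
    for s, t, _ in spec.coupling:
        if s != t:
            A[s, t] = 1
    return clustering(A)


def generate_cohort(
    base: GroundTruthSpec,
    n_per_group: int = 19,
    states: tuple[str, ...] = ("EO", "EC"),
    duration_s: float = 250.0,
    fs: float = 500.0,
    coupling_jitter: float = 0.2,
    subject_rewire_fraction: float = 0.2,
    recall_coupling_r: float = -0.6,
    effect_seed: int | None = None,
) -> Cohort:
    """Generate a two-group cohort of recordings with per-subject ground truth.

    Per-subject specs rewire a fraction of the template's coupling edges
    (individual topology) and jitter the coupling coefficients; the "Miners"
    group template first receives ``base.group_effect``.  Artifacts are
    injected when ``base.artifact_spec`` has non-zero rates.  Recall scores
    are generated with correlation ``recall_coupling_r`` to each subject's
    true clustering level (within group); the remaining psychometric columns
    are drawn around the group anchors.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    root = np.random.SeedSequence(base.seed)
    group_seeds = {g: s for g, s in zip(("Control", "Miners"), root.spawn(2))}
    psych_seed, = root.spawn(1)

    recordings: list[Recording] = []
    subject_specs: dict[str, GroundTruthSpec] = {}
    manifest_rows = []
    cc_true: dict[str, float] = {}

    for group in ("Control", "Miners"):
        gseq = group_seeds[group]
        template = base
        if group == "Miners" and base.group_effect is not None:
            # the removal selection defines the "Miners" population; pin it
            # with effect_seed to keep the scenario fixed across cohorts
            eff_rng = (np.random.default_rng(effect_seed)
                       if effect_seed is not None
                       else np.random.default_rng(gseq.spawn(1)[0]))
            template = _apply_group_effect(base, base.group_effect, eff_rng)
        subj_seqs = gseq.spawn(n_per_group)
        for si, sseq in enumerate(subj_seqs):
            subject_id = f"{'C' if group == 'Control' else 'M'}{si + 1:02d}"
            jit_seq, *state_seqs = sseq.spawn(1 + len(states))
            jit_rng = np.random.default_rng(jit_seq)
            sspec = _rewire_coupling(template, jit_rng, subject_rewire_fraction)
            sspec = _jitter_coupling(sspec, jit_rng, coupling_jitter)
            subject_specs[subject_id] = sspec
            cc_true[subject_id] = true_clustering(sspec)
            for state, stseq in zip(states, state_seqs):
                rng = np.random.default_rng(stseq)
                rec = generate_mvar_recording(
                    sspec, duration_s, fs, rng=rng,
                    subject_id=subject_id, group=group, state=state)
                if sspec.artifact_spec.any_active:
                    rec, _ = inject_artifacts(rec, sspec, rng=rng)
                recordings.append(rec)
                manifest_rows.append(
                    {"subject_id": subject_id, "group": group, "state": state,
                     "seed": base.seed})

    psych = _generate_psychometrics(
        subject_specs, cc_true, recall_coupling_r,
        np.random.default_rng(psych_seed))
    manifest = pd.DataFrame(manifest_rows)
    return Cohort(recordings, subject_specs, psych, manifest)


def _generate_psychometrics(
    subject_specs: dict[str, GroundTruthSpec],
    cc_true: dict[str, float],
    recall_r: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    groups = {sid: ("Control" if sid.startswith("C") else "Miners")
              for sid in subject_specs}
    for group in ("Control", "Miners"):
        sids = [s for s, g in groups.items() if g == group]
        cc = np.array([cc_true[s] for s in sids])
        z_cc = (cc - cc.mean()) / max(cc.std(), 1e-12)
        noise = rng.standard_normal(len(sids))
        noise = (noise - noise.mean()) / max(noise.std(), 1e-12)
        # exact in-sample correlation structure: recall_z ~ r*z_cc + sqrt(1-r^2)*e
        e = noise - (noise @ z_cc / max(z_cc @ z_cc, 1e-12)) * z_cc
        e = e / max(e.std(), 1e-12)
        recall_z = recall_r * z_cc + np.sqrt(1 - recall_r**2) * e
        anch = _PSYCH_ANCHORS[group]
        for i, sid in enumerate(sids):
            rows.append({
                "subject_id": sid, "group": group,
                "TMT_A": anch["TMT_A"][0] + anch["TMT_A"][1] * rng.standard_normal(),
                "TMT_B": anch["TMT_B"][0] + anch["TMT_B"][1] * rng.standard_normal(),
                "immediate_memory": anch["immediate_memory"][0]
                + anch["immediate_memory"][1] * rng.standard_normal(),
                "recall": anch["recall"][0] + anch["recall"][1] * recall_z[i],
                "true_clustering": cc_true[sid],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk I/O (FIF recordings + JSON ground truth + CSV manifest)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> pd.DataFrame:
    """Write recordings (FIF via MNE), ground truth (JSON) and manifest (CSV)."""
    import pathlib

    import mne

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for rec in cohort.recordings:
        info = mne.create_info(rec.channel_labels, rec.fs, ch_types="eeg")
        raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
        fname = out / f"{rec.subject_id}_{rec.state}_raw.fif"
        raw.save(fname, overwrite=True, verbose="error")
        files.append(str(fname.name))
    manifest = cohort.manifest.copy()
    manifest["file"] = files
    manifest.to_csv(out / "manifest.csv", index=False)
    cohort.psychometrics.to_csv(out / "psychometrics.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({sid: json.loads(s.to_json())
                   for sid, s in cohort.subject_specs.items()}, fh)
    return manifest
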