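"""Synthetic cohorts with planted pairwise, triadic, identity and behavior structure.

The generator emulates the statistical structure the downstream analyses are
designed to detect, without any imaging data:

* **pairs** — two regions share a Gaussian latent; a coupling ``c`` in [0, 1]
  is the latent variance share, so the planted Pearson correlation is ``c``.
* **triads** — three regions share, frame by frame, a concordant random sign
  ``s(t)`` (drawn from the fully coherent patterns ``(+,+,+)`` / ``(-,-,-)``)
  multiplied by independent per-region magnitudes ``|h(t)|``; with coupling
  ``c`` each member signal is ``sqrt(c) * s * |h| + sqrt(1 - c) * noise``.
  The construction elevates coherent triple co-fluctuations while leaking only
  weak pairwise correlation (``2 c / pi`` within the triad), so higher-order
  indicators should detect planted triads that pairwise ones largely miss.
* **task states** — frames are split into contiguous blocks of states; the
  shared triads of the spec are assigned round-robin to states and are active
  only in their state's frames, while shared pairs stay active in every state
  (pairwise couplings matched across states).
* **state assemblies** — alternatively (or additionally) each state owns a
  coherent assembly of ``assembly_size`` regions with a shared per-frame
  sign and *sustained* magnitudes (``|N(0,1)|`` offset by ``assembly_mean``
  standard deviations).  Sustained magnitudes make the edge and triangle
  co-fluctuation weights of the assembly nearly block-constant, emulating
  the sustained task-evoked coherence topography that recurrence-plot
  decoding exploits in real data.  Assemblies of different states overlap,
  and overlapping pairs keep the same coupling in every state where both
  nodes are active, so the pairwise structure is as matched across states
  as the construction permits; the triadic layout is what switches.
* **identity** — each subject carries its own node-disjoint triads (a random
  partition of the regions into triples), drawn once per subject from the
  cohort seed and reused in both sessions, with coupling
  ``identity_coupling * identity_strength``.  Identity triads use an
  *amplitude-compensated* concordant construction: with probability 1/2 the
  frame is fully concordant (shared sign, amplitude ``A``), otherwise a
  mixed sign pattern is drawn with amplitude ``B = sqrt(3) * A``.  Because
  mixed patterns have pairwise sign expectation -1/3, this choice makes the
  planted pairwise covariance exactly zero — the subject's fingerprint lives
  exclusively in third-order (concordance) statistics, where the signed
  triangle weights see a strong stable offset but node-level FC sees
  nothing.  Sessions differ only in their noise realizations.
* **behavior** — cognitive scores are linear read-outs of the brain feature
  matrix along planted salience directions plus Gaussian noise, rotated into
  ``n_behavior_scores`` columns with known loadings.

Randomness is split into a *structural* stream (cohort seed + subject id:
which triads a subject owns) and a *session* stream (fresh noise per
session), both derived through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .behavior import CognitiveScoreTable
from .connectivity import NETWORKS, NetworkAssignment
from .decoding import Partition
from .errors import DimensionError
from .panel import TimeSeriesPanel

__all__ = [
    "CohortSpec",
    "PlantedBehavior",
    "gen_subject_panel",
    "gen_task_labels",
    "gen_behavior",
    "default_network_table",
    "task_cohort_spec",
    "identity_cohort_spec",
]

_STRUCTURAL_STREAM = 101
_SESSION_STREAM = 202
_BEHAVIOR_STREAM = 303

_SESSIONS = ("test", "retest")

# the six mixed (discordant) sign patterns over a triple
_MIXED_PATTERNS = np.array([
    [1, 1, -1], [1, -1, 1], [-1, 1, 1],
    [-1, -1, 1], [-1, 1, -1], [1, -1, -1],
], dtype=np.float64)


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Couplings are variance shares in [0, 1].  ``triad_list`` entries are
    ``(i, j, k, coupling)``; ``pair_list`` entries are ``(i, j, coupling)``.
    """

    n_regions: int
    n_frames: int
    n_subjects: int = 1
    n_states: int = 1
    block_length: int | None = None
    triad_list: list[tuple[int, int, int, float]] = field(default_factory=list)
    pair_list: list[tuple[int, int, float]] = field(default_factory=list)
    identity_strength: float = 0.0
    n_identity_triads: int | None = None   # default: floor(n_regions / 3)
    identity_coupling: float = 0.9
    identity_mean: float = 2.0
    assembly_size: int = 0
    assembly_coupling: float = 0.9
    assembly_mean: float = 4.0
    behavior_salience: np.ndarray | None = None     # (K, F) rows scaled by strength
    behavior_noise_sd: float = 0.1
    n_behavior_scores: int = 10
    network_table: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3 or self.n_frames < 1 or self.n_subjects < 1:
            raise DimensionError("need n_regions >= 3, n_frames >= 1, n_subjects >= 1")
        if self.block_length is None:
            self.block_length = self.n_frames // self.n_states
        if self.block_length * self.n_states > self.n_frames:
            raise DimensionError("block_length * n_states exceeds n_frames")
        for i, j, k, c in self.triad_list:
            if not (0 <= i < j < k < self.n_regions):
                raise IndexError(f"invalid triad ({i},{j},{k}) for N={self.n_regions}")
            if not 0.0 <= c <= 1.0:
                raise DimensionError(f"triad coupling {c} outside [0, 1]")
        for i, j, c in self.pair_list:
            if not (0 <= i < j < self.n_regions):
                raise IndexError(f"invalid pair ({i},{j}) for N={self.n_regions}")
            if not 0.0 <= c <= 1.0:
                raise DimensionError(f"pair coupling {c} outside [0, 1]")
        if not 0.0 <= self.identity_strength <= 1.0:
            raise DimensionError("identity_strength must lie in [0, 1]")
        if self.assembly_size and not 3 <= self.assembly_size <= self.n_regions:
            raise DimensionError("assembly_size must lie in [3, n_regions]")
        if not 0.0 <= self.assembly_coupling <= 1.0:
            raise DimensionError("assembly coupling outside [0, 1]")
        if not self.network_table:
            self.network_table = default_network_table(self.n_regions)
        if len(self.network_table) != self.n_regions:
            raise DimensionError("network table does not cover every region")

    @property
    def assignment(self) -> NetworkAssignment:
        return NetworkAssignment(list(self.network_table))


@dataclass
class PlantedBehavior:
    """Ground truth recorded by :func:`gen_behavior` for recovery tests."""

    saliences: np.ndarray   # (K, F) unit rows
    strengths: np.ndarray   # (K,)
    loadings: np.ndarray    # (K, Q) orthonormal rows
    latents: np.ndarray     # (S, K)


def default_network_table(n_regions: int) -> list[str]:
    """Contiguous chunks over the eight canonical functional systems."""
    reps = int(np.ceil(n_regions / len(NETWORKS)))
    table = [net for net in NETWORKS for _ in range(reps)]
    return table[:n_regions]


def gen_task_labels(spec: CohortSpec) -> Partition:
    """Per-frame state labels: contiguous blocks of ``block_length`` frames,
    states in order, cycling if frames remain after one pass."""
    n_blocks = int(np.ceil(spec.n_frames / spec.block_length))
    labels = np.repeat(np.arange(n_blocks) % spec.n_states, spec.block_length)
    return Partition(labels[: spec.n_frames])


def _subject_triads(spec: CohortSpec, subject_id: int) -> list[tuple[int, int, int, float]]:
    """Node-disjoint identity triads from a subject-specific region partition."""
    c = spec.identity_coupling * spec.identity_strength
    n_tri = spec.n_identity_triads
    if n_tri is None:
        n_tri = spec.n_regions // 3
    if c == 0.0 or n_tri == 0:
        return []
    if 3 * n_tri > spec.n_regions:
        raise DimensionError("n_identity_triads exceeds floor(n_regions / 3)")
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _STRUCTURAL_STREAM, subject_id]))
    perm = rng.permutation(spec.n_regions)
    return [tuple(sorted(int(v) for v in perm[3 * i: 3 * i + 3])) + (c,)
            for i in range(n_tri)]


def gen_subject_panel(spec: CohortSpec, subject_id: int, session: str = "test",
                      rng_seed: int | None = None) -> TimeSeriesPanel:
    """One subject's region x time panel for one session.

    The structural draw (the subject's own triads) depends only on the cohort
    seed and the subject id; latent and noise realizations come from the
    session stream (or ``rng_seed`` when given), so test and retest share
    structure but not noise.
    """
    if session not in _SESSIONS:
        raise ValueError(f"session must be one of {_SESSIONS}")
    if not 0 <= subject_id < spec.n_subjects:
        raise IndexError(f"subject {subject_id} outside cohort of {spec.n_subjects}")
    if rng_seed is None:
        noise_rng = np.random.default_rng(np.random.SeedSequence(
            [spec.seed, _SESSION_STREAM, subject_id, _SESSIONS.index(session)]))
    else:
        noise_rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed)]))

    n, t = spec.n_regions, spec.n_frames
    labels = gen_task_labels(spec).labels
    x = np.zeros((n, t))
    var_acc = np.zeros((n, t))

    # shared pairs: active in every state
    for a, b, c in spec.pair_list:
        g = noise_rng.standard_normal(t)
        amp = np.sqrt(c)
        for node in (a, b):
            x[node] += amp * g
            var_acc[node] += c

    # shared triads (concordant-sign construction): round-robin over states
    shared = [(tri, s % spec.n_states) for s, tri in enumerate(spec.triad_list)]
    for (a, b, cc, c), state in shared:
        sign = noise_rng.choice([-1.0, 1.0], size=t)
        mag = np.abs(noise_rng.standard_normal((3, t)))
        active = labels == state
        amp = np.sqrt(c) * active
        for m, node in enumerate((a, b, cc)):
            x[node] += amp * sign * mag[m]
            var_acc[node] += c * active

    # subject identity triads (amplitude-compensated concordant construction,
    # always active): mixed-pattern amplitude sqrt(3) cancels the pairwise
    # covariance exactly (mixed sign patterns have E[s_a s_b] = -1/3)
    m_id = spec.identity_mean
    b_amp = np.sqrt(3.0)
    z_norm = np.sqrt(0.5 * (1.0 + b_amp**2)
                     * (m_id**2 + 2.0 * m_id * np.sqrt(2.0 / np.pi) + 1.0))
    for a, b, cc, c in _subject_triads(spec, subject_id):
        conc = noise_rng.random(t) < 0.5
        shared = noise_rng.choice([-1.0, 1.0], size=t)
        mix = _MIXED_PATTERNS[noise_rng.integers(0, 6, size=t)].T  # (3, T)
        signs = np.where(conc, shared, mix)
        amp = np.sqrt(c) * np.where(conc, 1.0, b_amp) / z_norm
        mag = m_id + np.abs(noise_rng.standard_normal((3, t)))
        for m, node in enumerate((a, b, cc)):
            x[node] += amp * signs[m] * mag[m]
            var_acc[node] += c

    # state assemblies (sustained-magnitude construction)
    m_off = spec.assembly_mean
    norm = np.sqrt(m_off**2 + 2.0 * m_off * np.sqrt(2.0 / np.pi) + 1.0)
    for nodes, state in _assemblies(spec):
        active = labels == state
        sign = noise_rng.choice([-1.0, 1.0], size=t)
        mags = (m_off + np.abs(noise_rng.standard_normal((nodes.size, t)))) / norm
        amp = np.sqrt(spec.assembly_coupling) * active
        for m, node in enumerate(nodes):
            x[node] += amp * sign * mags[m]
            var_acc[node] += spec.assembly_coupling * active

    resid = np.sqrt(np.clip(1.0 - var_acc, 0.05, None))
    x += resid * noise_rng.standard_normal((n, t))
    return TimeSeriesPanel(x)


def _assemblies(spec: CohortSpec) -> list[tuple[np.ndarray, int]]:
    """Per-state coherent assemblies: (member regions, state).

    Structural draws come from the cohort seed only, so every subject shares
    the same task-assembly layout.
    """
    if spec.assembly_size == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 404]))
    return [(np.sort(rng.permutation(spec.n_regions)[: spec.assembly_size]), state)
            for state in range(spec.n_states)]


def gen_behavior(spec: CohortSpec, features: np.ndarray) -> tuple[CognitiveScoreTable, PlantedBehavior]:
    """Cognitive scores as noisy linear read-outs of the brain features.

    ``features`` is a subjects x F matrix (one static connectivity vector per
    subject).  Each planted component ``c`` contributes
    ``strength_c * standardized(X_z @ w_c) (x) u_c`` where ``w_c`` is the unit
    salience direction and the loadings ``u_c`` are deterministic orthonormal
    vectors over the ``n_behavior_scores`` columns; independent Gaussian noise
    with ``behavior_noise_sd`` is added everywhere.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] != spec.n_subjects:
        raise DimensionError("features must be a subjects x F matrix")
    s, f = features.shape
    q = spec.n_behavior_scores
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _BEHAVIOR_STREAM]))

    if spec.behavior_salience is None:
        sal = np.zeros((0, f))
    else:
        sal = np.atleast_2d(np.asarray(spec.behavior_salience, dtype=np.float64))
        if sal.shape[1] != f:
            raise DimensionError(
                f"behavior salience length {sal.shape[1]} != feature count {f}")
    k = sal.shape[0]
    strengths = np.linalg.norm(sal, axis=1)
    units = sal / strengths[:, None] if k else sal

    # deterministic orthonormal loadings over the score columns
    basis = np.linalg.qr(rng.standard_normal((q, q)))[0]
    loadings = basis[:, :k].T if k else np.zeros((0, q))

    sd = features.std(axis=0, ddof=1)
    safe = np.where(sd == 0.0, 1.0, sd)
    xz = (features - features.mean(axis=0)) / safe

    y = rng.standard_normal((s, q)) * spec.behavior_noise_sd
    latents = np.zeros((s, k))
    for c in range(k):
        lat = xz @ units[c]
        lat_sd = lat.std(ddof=1)
        if lat_sd > 0:
            lat = (lat - lat.mean()) / lat_sd
        latents[:, c] = lat
        y += strengths[c] * np.outer(lat, loadings[c])

    table = CognitiveScoreTable(y)
    return table, PlantedBehavior(saliences=units, strengths=strengths,
                                  loadings=loadings, latents=latents)


# ---------------------------------------------------------------------------
# study-condition builders


def task_cohort_spec(n_regions: int = 20, n_frames: int = 400, n_states: int = 4,
                     assembly_size: int = 12, assembly_coupling: float = 0.9,
                     assembly_mean: float = 4.0, seed: int = 0,
                     **kwargs) -> CohortSpec:
    """Task-decoding cohort: one coherent assembly per state.

    Each state activates the full triad set of a 12-region assembly (drawn
    from a seeded permutation), so states switch which triads co-fluctuate
    coherently.  Coupling 0.9 with a 4-s.d. sustained magnitude emulates a
    strongly task-locked coherence topography; no pair-specific couplings
    are planted, and overlapping assembly pairs keep identical coupling in
    every state where both members are active.
    """
    return CohortSpec(n_regions=n_regions, n_frames=n_frames, n_states=n_states,
                      assembly_size=assembly_size,
                      assembly_coupling=assembly_coupling,
                      assembly_mean=assembly_mean, seed=seed, **kwargs)


def identity_cohort_spec(n_regions: int = 12, n_frames: int = 200,
                         n_subjects: int = 20, identity_strength: float = 1.0,
                         identity_coupling: float = 0.9,
                         seed: int = 0, **kwargs) -> CohortSpec:
    """Fingerprinting cohort: identity planted purely in subject-specific
    triadic (third-order) structure, with zero planted pairwise covariance."""
    return CohortSpec(n_regions=n_regions, n_frames=n_frames,
                      n_subjects=n_subjects, identity_strength=identity_strength,
                      identity_coupling=identity_coupling, seed=seed, **kwargs)
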