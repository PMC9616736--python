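"""Synthetic data generators with planted ground truth.

Three generators emulate the statistical structure the downstream stages
assume:

* :func:`gen_counts` — a gene x cell UMI matrix with zero-inflated
  negative-binomial (ZINB) counts, class-specific marker programs,
  planted doublets (sums of two singlets of different classes), planted
  low-quality barcodes, and a multiplicative condition effect on chosen
  genes.
* :func:`gen_traces` — fluorescence time series with a sustained step
  response during a drug window, planted per-trace response categories.
* :func:`gen_anatomy` — a branched skeleton (node cloud with radii) and
  synapse point clouds whose distance-to-process offsets differ by
  transmitter, with planted tripartite-synapse (TPS) partners.

Every generator is a pure function of its :class:`SimConfig`: the same
config (including seed) yields identical outputs.  Each generator draws
from an independent seed stream so that, e.g., changing the trace spec
never perturbs the count matrix.

Deliberate simplifications (documented in the methods note): class
markers are mutually exclusive between classes (no ambient
contamination), trace responses are flat steps rather than kinetic
transients, and the skeleton is a random walk rather than a biological
arbor — only node positions and radii matter downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .errors import ConfigError

__all__ = [
    "ClassSpec",
    "TraceSpec",
    "AnatomySpec",
    "SimConfig",
    "GroundTruth",
    "TraceSet",
    "Skeleton",
    "gen_counts",
    "gen_traces",
    "gen_anatomy",
]

# Seed-stream indices: one independent stream per generator.
_COUNTS_STREAM = 0
_TRACES_STREAM = 1
_ANATOMY_STREAM = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class ClassSpec:
    """One planted cell class: its abundance and marker program.

    ``marker_mean`` is the NB mean UMI count of each marker gene in cells
    of this class; outside the class marker genes are exactly zero
    (markers of fast-transmitter classes and glia are mutually exclusive
    in the fly brain, which is what makes co-expression a doublet
    signature).
    """

    name: str
    fraction: float
    markers: tuple = ()
    marker_mean: float = 50.0
    # breadth/strength of the class's expression program beyond its
    # markers (a block of filler genes with elevated NB mean), giving
    # classes a transcriptomic identity like real cell types
    n_program_genes: int = 25
    program_log2fc: float = 1.5


@dataclass
class TraceSpec:
    """Planted calcium-trace structure.

    Durations in seconds, amplitudes in dF/F0 units (a step of
    ``amplitude * f0`` raw fluorescence is added during the drug window).
    """

    frame_rate: float = 5.92
    baseline_s: float = 20.0
    drug_s: float = 25.0
    post_s: float = 30.0
    noise_sd: float = 0.05
    f0: float = 100.0
    n_traces: int = 300
    amplitudes: dict = field(
        default_factory=lambda: {"activated": 0.5, "inhibited": -0.5, "no_change": 0.0}
    )
    fractions: dict = field(
        default_factory=lambda: {"activated": 0.3, "inhibited": 0.2, "no_change": 0.5}
    )
    drug: str = "glutamate"


@dataclass
class AnatomySpec:
    """Planted skeleton / synapse-cloud structure.  All lengths in nm."""

    n_nodes: int = 500
    branch_prob: float = 0.08
    step_sd: float = 150.0
    fine_fraction: float = 0.85
    fine_radius: tuple = (40.0, 280.0)
    coarse_radius: tuple = (350.0, 900.0)
    synapse_counts: dict = field(
        default_factory=lambda: {"glutamate": 300, "GABA": 200, "acetylcholine": 300}
    )
    distance_offsets: dict = field(
        default_factory=lambda: {"glutamate": 900.0, "GABA": 950.0, "acetylcholine": 1100.0}
    )
    distance_sd: float = 300.0
    score_fail_fraction: float = 0.0
    tps_fraction: float = 0.1
    astrocyte_id: str = "astro-1"


@dataclass
class SimConfig:
    """Full simulation configuration.

    ``mu_range`` gives the log-uniform range of baseline per-gene NB
    means; ``theta`` and ``pi`` the shared NB dispersion and
    zero-inflation probability (marker genes use ``marker_theta`` and no
    zero inflation so that planted class programs are unambiguous).
    ``de_spec`` lists (gene, log2 fold change) pairs applied
    multiplicatively to the NB mean in the second condition.
    ``n_qc_violators`` cells have their counts binomially thinned by
    ``qc_violator_scale`` so they fall below the minimum-feature QC
    threshold.
    """

    seed: int = 0
    n_genes: int = 2000
    n_cells: int = 1000
    class_spec: list = field(
        default_factory=lambda: [
            ClassSpec("cholinergic", 0.30, ("VAChT",)),
            ClassSpec("glutamatergic", 0.25, ("VGlut",)),
            ClassSpec("GABAergic", 0.20, ("Gad1",)),
            ClassSpec("glia", 0.25, ("nrv2",)),
        ]
    )
    doublet_rate: float = 0.0
    n_qc_violators: int = 0
    qc_violator_scale: float = 0.02
    mu_range: tuple = (0.05, 2.0)
    theta: float = 2.0
    pi: float = 0.1
    marker_theta: float = 20.0
    conditions: tuple = ("sated", "dehydrated_12h")
    de_spec: list = field(default_factory=list)
    trace_spec: TraceSpec = field(default_factory=TraceSpec)
    anatomy_spec: AnatomySpec = field(default_factory=AnatomySpec)

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ConfigError("n_genes and n_cells must be positive")
        total = sum(c.fraction for c in self.class_spec)
        if total > 1.0 + 1e-9 or any(c.fraction < 0 for c in self.class_spec):
            raise ConfigError(f"class fractions must be non-negative and sum to <= 1 (got {total:.3f})")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ConfigError("doublet_rate must be in [0, 1)")
        if not (0.0 <= self.pi < 1.0):
            raise ConfigError("zero-inflation pi must be in [0, 1)")
        if self.theta <= 0 or self.marker_theta <= 0:
            raise ConfigError("NB dispersion theta must be > 0")
        if self.mu_range[0] <= 0 or self.mu_range[1] < self.mu_range[0]:
            raise ConfigError("mu_range must be positive and increasing")
        if self.n_qc_violators < 0 or self.n_qc_violators >= self.n_cells:
            raise ConfigError("n_qc_violators must be in [0, n_cells)")
        ts = self.trace_spec
        if ts.frame_rate <= 0:
            raise ConfigError("trace frame rate must be positive")
        if min(ts.baseline_s, ts.drug_s, ts.post_s) <= 0:
            raise ConfigError("trace window durations must be positive")
        if abs(sum(ts.fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("trace category fractions must sum to 1")
        an = self.anatomy_spec
        if an.n_nodes < 2:
            raise ConfigError("anatomy needs at least 2 skeleton nodes")
        if any(c < 0 for c in an.synapse_counts.values()):
            raise ConfigError("synapse counts must be non-negative")
        if not (0.0 <= an.tps_fraction <= 1.0):
            raise ConfigError("tps_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted labels for every generated unit.  Fields are populated by
    whichever generator produced the object; unused fields stay None."""

    cell_class: Optional[np.ndarray] = None
    is_doublet: Optional[np.ndarray] = None
    is_qc_violator: Optional[np.ndarray] = None
    de_genes: Optional[dict] = None
    trace_category: Optional[np.ndarray] = None
    transmitter_offsets: Optional[dict] = None
    tps_mask: Optional[np.ndarray] = None
    synapse_passes_scores: Optional[np.ndarray] = None

    def to_json(self, path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in asdict(self).items()}, fh, indent=1)


@dataclass
class TraceSet:
    """A stack of raw fluorescence traces sharing one acquisition setup."""

    values: np.ndarray  # (n_traces, n_frames), raw F in a.u.
    frame_rate: float
    onset_s: float
    offset_s: float
    cell_ids: list
    drug: str = "glutamate"
    state: Optional[str] = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cell, frame, F) as written to CSV."""
        n, t = self.values.shape
        return pd.DataFrame(
            {
                "cell": np.repeat(self.cell_ids, t),
                "frame": np.tile(np.arange(t), n),
                "F": self.values.ravel(),
            }
        )


@dataclass
class Skeleton:
    """Astrocyte skeleton: node table with parent links and radii (nm)."""

    nodes: pd.DataFrame  # columns: node_id, parent_id, x, y, z, radius
    astrocyte_id: str = "astro-1"

    def __post_init__(self):
        req = {"node_id", "parent_id", "x", "y", "z", "radius"}
        missing = req - set(self.nodes.columns)
        if missing:
            raise ConfigError(f"skeleton node table missing columns: {sorted(missing)}")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _gene_names(config: SimConfig) -> list:
    """Marker genes first, then QC-metric gene families, then filler genes."""
    markers = []
    for cs in config.class_spec:
        for m in cs.markers:
            if m not in markers:
                markers.append(m)
    names = list(markers)
    names += [f"mt:gene{i}" for i in range(10)]
    names += [f"lncRNA:rRNA:{i}" for i in range(5)]
    names += [f"RpL{i}" for i in range(15)] + [f"RpS{i}" for i in range(15)]
    n_fill = config.n_genes - len(names)
    if n_fill < 0:
        raise ConfigError("n_genes too small for the marker and housekeeping gene sets")
    names += [f"gene{i:04d}" for i in range(n_fill)]
    return names


def _draw_zinb(rng, mu, theta, pi):
    """Vectorized ZINB draw; mu, theta, pi broadcastable arrays."""
    mu = np.asarray(mu, float)
    out = np.zeros(np.broadcast_shapes(mu.shape), dtype=np.int64)
    pos = mu > 0
    if np.any(pos):
        p = theta / (theta + mu)
        out = rng.negative_binomial(np.broadcast_to(theta, mu.shape), p)
        out[~pos] = 0
    if np.any(np.asarray(pi) > 0):
        drop = rng.random(mu.shape) < pi
        out[drop] = 0
    return out


def gen_counts(config: SimConfig):
    """Generate (counts AnnData, cell table, ground truth).

    The AnnData holds raw UMI counts (cells x genes, sparse) with cell
    metadata in ``.obs``; normalized layers are added downstream by
    :mod:`thirststate.sc_qc`.  Doublets are sums of the raw counts of two
    singlets of different classes.  Genes named in ``de_spec`` have their
    NB mean multiplied by ``2**log2fc`` in the second condition.
    """
    config.validate()
    rng = _rng(config.seed, _COUNTS_STREAM)

    genes = _gene_names(config)
    n_genes, n_cells = config.n_genes, config.n_cells
    gene_idx = {g: i for i, g in enumerate(genes)}

    # per-gene baseline parameters
    mu0 = np.exp(rng.uniform(np.log(config.mu_range[0]), np.log(config.mu_range[1]), n_genes))
    # lift QC-family genes so the mito/rRNA/ribo fractions are exercised
    for prefix, lift in (("mt:", 8.0), ("lncRNA:rRNA", 2.0), ("RpL", 4.0), ("RpS", 4.0)):
        sel = [i for i, g in enumerate(genes) if g.startswith(prefix)]
        mu0[sel] *= lift
    theta = np.full(n_genes, float(config.theta))
    pi = np.full(n_genes, float(config.pi))
    marker_set = set()
    for cs in config.class_spec:
        marker_set.update(cs.markers)
    for m in marker_set:
        mu0[gene_idx[m]] = 0.0  # markers only expressed via class programs
        theta[gene_idx[m]] = config.marker_theta
        pi[gene_idx[m]] = 0.0

    n_doublets = int(round(config.doublet_rate * n_cells))
    n_singlets = n_cells - n_doublets

    # class assignment for singlets; leftover fraction becomes "other"
    fractions = np.array([cs.fraction for cs in config.class_spec])
    names = [cs.name for cs in config.class_spec]
    probs = np.append(fractions, max(0.0, 1.0 - fractions.sum()))
    probs /= probs.sum()
    labels = rng.choice(names + ["other"], size=n_singlets, p=probs)
    conditions = rng.permutation(
        np.resize(np.asarray(config.conditions, dtype=object), n_singlets)
    )

    de_genes = {g: float(lfc) for g, lfc in config.de_spec}
    for g in de_genes:
        if g not in gene_idx:
            raise ConfigError(f"de_spec gene not in gene set: {g}")

    # disjoint per-class program gene blocks, drawn from the filler genes
    filler = [i for i, g in enumerate(genes) if g.startswith("gene")]
    program_genes = {}
    cursor = 0
    for cs in config.class_spec:
        take = filler[cursor : cursor + cs.n_program_genes]
        if len(take) < cs.n_program_genes:
            raise ConfigError("not enough filler genes for the class programs")
        program_genes[cs.name] = take
        cursor += cs.n_program_genes

    # build per-cell mean matrix then draw
    mu = np.tile(mu0, (n_singlets, 1))
    for cs in config.class_spec:
        in_class = labels == cs.name
        for m in cs.markers:
            mu[in_class, gene_idx[m]] = cs.marker_mean
        if cs.n_program_genes:
            mu[np.ix_(in_class, program_genes[cs.name])] *= 2.0**cs.program_log2fc
    cond_b = conditions == config.conditions[1]
    for g, lfc in de_genes.items():
        mu[cond_b, gene_idx[g]] *= 2.0**lfc
    counts = _draw_zinb(rng, mu, theta[None, :], pi[None, :])

    # doublets: sums of two singlets of different classes
    is_doublet = np.zeros(n_cells, dtype=bool)
    cell_class = np.empty(n_cells, dtype=object)
    cell_cond = np.empty(n_cells, dtype=object)
    cell_class[:n_singlets] = labels
    cell_cond[:n_singlets] = conditions
    doublet_rows = []
    for d in range(n_doublets):
        while True:
            i, j = rng.choice(n_singlets, size=2, replace=False)
            if labels[i] != labels[j]:
                break
        doublet_rows.append(counts[i] + counts[j])
        cell_class[n_singlets + d] = f"{labels[i]}+{labels[j]}"
        cell_cond[n_singlets + d] = conditions[i]
        is_doublet[n_singlets + d] = True
    if doublet_rows:
        counts = np.vstack([counts, np.array(doublet_rows)])

    # planted QC violators: binomial thinning of singlet counts
    is_violator = np.zeros(n_cells, dtype=bool)
    if config.n_qc_violators:
        viol = rng.choice(n_singlets, size=config.n_qc_violators, replace=False)
        counts[viol] = rng.binomial(counts[viol], config.qc_violator_scale)
        is_violator[viol] = True

    order = rng.permutation(n_cells)
    counts = counts[order]
    cell_class = cell_class[order]
    cell_cond = cell_cond[order]
    is_doublet = is_doublet[order]
    is_violator = is_violator[order]

    obs = pd.DataFrame(
        {
            "condition": cell_cond.astype(str),
            "replicate": rng.integers(1, 3, n_cells),
            "sex": rng.choice(["F", "M"], n_cells),
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    adata = AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(
            {"mu_base": mu0, "theta": theta, "pi": pi}, index=genes
        ),
    )
    truth = GroundTruth(
        cell_class=cell_class,
        is_doublet=is_doublet,
        is_qc_violator=is_violator,
        de_genes=de_genes,
    )
    return adata, adata.obs, truth


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def gen_traces(config: SimConfig):
    """Generate a :class:`TraceSet` plus ground-truth response categories.

    Each trace is Gaussian noise around ``f0``; activated / inhibited
    traces additionally carry a sustained step of ``amplitude * f0``
    during the drug window.
    """
    config.validate()
    ts = config.trace_spec
    rng = _rng(config.seed, _TRACES_STREAM)

    n = ts.n_traces
    total_s = ts.baseline_s + ts.drug_s + ts.post_s
    n_frames = int(total_s * ts.frame_rate)  # floor: partial frames are not acquired
    onset = ts.baseline_s
    offset = ts.baseline_s + ts.drug_s
    onset_idx = int(round(onset * ts.frame_rate))
    offset_idx = int(round(offset * ts.frame_rate))

    cats = list(ts.fractions)
    categories = rng.choice(cats, size=n, p=[ts.fractions[c] for c in cats])
    values = ts.f0 * (1.0 + rng.normal(0.0, ts.noise_sd, (n, n_frames)))
    for c in cats:
        amp = ts.amplitudes.get(c, 0.0)
        if amp:
            values[categories == c, onset_idx:offset_idx] += amp * ts.f0

    traces = TraceSet(
        values=values,
        frame_rate=ts.frame_rate,
        onset_s=onset,
        offset_s=offset,
        cell_ids=[f"roi{i:04d}" for i in range(n)],
        drug=ts.drug,
    )
    return traces, GroundTruth(trace_category=categories)


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def gen_anatomy(config: SimConfig):
    """Generate (Skeleton, synapse table, ground truth).

    The skeleton is a seeded branched random walk; synapses of each
    transmitter are placed at (offset + Gaussian noise) nm from a random
    fine node along a random direction.  A ``tps_fraction`` of synapses
    list the astrocyte as a postsynaptic partner.
    """
    config.validate()
    an = config.anatomy_spec
    rng = _rng(config.seed, _ANATOMY_STREAM)

    n = an.n_nodes
    pos = np.zeros((n, 3))
    parent = np.full(n, -1, dtype=int)
    for i in range(1, n):
        parent[i] = i - 1 if rng.random() > an.branch_prob else int(rng.integers(0, i))
        pos[i] = pos[parent[i]] + rng.normal(0.0, an.step_sd, 3)
    fine = rng.random(n) < an.fine_fraction
    radius = np.where(
        fine,
        rng.uniform(*an.fine_radius, n),
        rng.uniform(*an.coarse_radius, n),
    )
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(1, n + 1),
            "parent_id": np.where(parent < 0, -1, parent + 1),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "radius": radius,
        }
    )
    skeleton = Skeleton(nodes=nodes, astrocyte_id=an.astrocyte_id)

    fine_pos = pos[radius < 300.0]
    if len(fine_pos) == 0:
        raise ConfigError("anatomy spec produced no fine (<300 nm radius) nodes")

    rows = []
    for transmitter, count in an.synapse_counts.items():
        offset = an.distance_offsets.get(transmitter, 1000.0)
        anchors = fine_pos[rng.integers(0, len(fine_pos), count)]
        direction = rng.normal(size=(count, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        dist = np.clip(offset + rng.normal(0.0, an.distance_sd, count), 0.0, None)
        xyz = anchors + direction * dist[:, None]
        for k in range(count):
            rows.append(
                {
                    "pre_id": f"n{rng.integers(10_000, 99_999)}",
                    "post_ids": f"n{rng.integers(10_000, 99_999)}",
                    "x": xyz[k, 0],
                    "y": xyz[k, 1],
                    "z": xyz[k, 2],
                    "transmitter": transmitter,
                }
            )
    synapses = pd.DataFrame(rows)
    m = len(synapses)

    passes = rng.random(m) >= an.score_fail_fraction
    cleft = np.where(passes, rng.uniform(50, 100, m), rng.uniform(0, 50, m))
    conn = np.where(passes, rng.uniform(33, 100, m), rng.uniform(0, 33, m))
    synapses["cleft_score"] = cleft
    synapses["connection_score"] = conn

    tps = rng.random(m) < an.tps_fraction
    synapses.loc[tps, "post_ids"] = synapses.loc[tps, "post_ids"] + ";" + an.astrocyte_id

    truth = GroundTruth(
        transmitter_offsets=dict(an.distance_offsets),
        tps_mask=tps,
        synapse_passes_scores=passes,
    )
    return skeleton, synapses, truth
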