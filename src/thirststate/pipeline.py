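"""End-to-end pipeline orchestration with manifest tracking.

A run is described by a single YAML (or dict) config:

.. code-block:: yaml

    seed: 1
    stages: [simulate, qc, fuse, de, calcium, vicinity]
    simulate:
      n_cells: 200
      n_genes: 600
      doublet_rate: 0.04

Stages execute in declared order, each reading only files previously
written into the output directory, so deleting downstream outputs and
re-running those stages reproduces them byte-for-byte.  The global seed
fans out deterministically into one sub-seed per stage.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from . import behavior, calcium, cluster_fusion, io, sc_qc, synthetic_data, vicinity, zinb_de

__all__ = ["RunManifest", "run_pipeline", "stage_seed", "load_config"]

KNOWN_STAGES = ("simulate", "qc", "fuse", "de", "calcium", "vicinity")
_TOP_KEYS = {"seed", "stages"} | set(KNOWN_STAGES)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list
    version: str
    files: dict = field(default_factory=dict)  # stage -> {path: n_records}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def load_config(config) -> dict:
    if isinstance(config, dict):
        cfg = config
    else:
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    bad = sorted(set(cfg) - _TOP_KEYS)
    if bad:
        raise ConfigError(f"unknown config key(s): {bad}")
    stages = cfg.get("stages")
    if not stages or not isinstance(stages, list):
        raise ConfigError("config must list at least one stage under 'stages'")
    unknown = sorted(set(stages) - set(KNOWN_STAGES))
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) derived from the global
    seed, so stages can be re-run independently."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sim_config(cfg: dict, seed: int) -> synthetic_data.SimConfig:
    sim = dict(cfg.get("simulate") or {})
    de_spec = [tuple(x) for x in sim.pop("de", [])]
    allowed = {
        "n_genes", "n_cells", "doublet_rate", "n_qc_violators",
        "qc_violator_scale", "theta", "pi",
    }
    bad = sorted(set(sim) - allowed)
    if bad:
        raise ConfigError(f"unknown simulate key(s): {bad}")
    return synthetic_data.SimConfig(seed=seed, de_spec=de_spec, **sim)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, outdir, seed):
    sc = _sim_config(cfg, seed)
    adata, _, truth = synthetic_data.gen_counts(sc)
    traces, ttruth = synthetic_data.gen_traces(sc)
    skel, synapses, atruth = synthetic_data.gen_anatomy(sc)

    counts_dir = os.path.join(outdir, "counts")
    io.write_counts(adata, counts_dir)
    truth.to_json(os.path.join(outdir, "truth_counts.json"))
    io.write_traces(traces, os.path.join(outdir, "traces.csv"))
    ttruth.to_json(os.path.join(outdir, "truth_traces.json"))
    vicinity.write_swc(skel, os.path.join(outdir, "skeleton.swc"))
    synapses.to_csv(os.path.join(outdir, "synapses.csv"), index=False)
    atruth.to_json(os.path.join(outdir, "truth_anatomy.json"))
    with open(os.path.join(outdir, "sim_meta.json"), "w") as fh:
        json.dump(
            {
                "frame_rate": traces.frame_rate,
                "onset_s": traces.onset_s,
                "offset_s": traces.offset_s,
                "drug": traces.drug,
                "astrocyte_id": skel.astrocyte_id,
            },
            fh,
        )
    return {
        os.path.join(counts_dir, "matrix.mtx"): int(adata.n_obs),
        os.path.join(outdir, "traces.csv"): len(traces.cell_ids),
        os.path.join(outdir, "skeleton.swc"): len(skel.nodes),
        os.path.join(outdir, "synapses.csv"): len(synapses),
        os.path.join(outdir, "sim_meta.json"): 1,
        os.path.join(outdir, "truth_counts.json"): 1,
        os.path.join(outdir, "truth_traces.json"): 1,
        os.path.join(outdir, "truth_anatomy.json"): 1,
    }


def _stage_qc(cfg, outdir, seed):
    adata = io.read_counts(os.path.join(outdir, "counts"))
    sc_qc.compute_qc_metrics(adata)
    keep = sc_qc.filter_barcodes(adata.obs)
    sc_qc.lognormalize(adata)
    thr = sc_qc.MarkerThresholds(
        class_markers=dict(
            (cfg.get("qc") or {}).get(
                "marker_thresholds",
                {"nrv2": 3.0, "VAChT": 1.5, "VGlut": 2.1, "Gad1": 2.3},
            )
        )
    )
    expr = sc_qc.marker_frame(adata, list(thr.class_markers), layer="lognorm")
    dmask, reasons = sc_qc.flag_coexpression_doublets(expr, thr)
    final, summary = sc_qc.merge_doublet_calls(dmask)
    out = pd.DataFrame(
        {"keep_qc": keep, "doublet": final, "reason": reasons.to_numpy()},
        index=adata.obs_names,
    )
    path = os.path.join(outdir, "qc_calls.csv")
    out.to_csv(path)
    with open(os.path.join(outdir, "qc_summary.json"), "w") as fh:
        json.dump(summary, fh)
    return {path: len(out), os.path.join(outdir, "qc_summary.json"): 1}


def _kept_cells(outdir):
    calls = pd.read_csv(os.path.join(outdir, "qc_calls.csv"), index_col=0)
    return calls.index[calls["keep_qc"] & ~calls["doublet"]]


def _marker_labels(adata, thr: "sc_qc.MarkerThresholds"):
    expr = sc_qc.marker_frame(adata, list(thr.class_markers), layer="lognorm")
    fired = np.column_stack(
        [expr[g].to_numpy() > t for g, t in thr.class_markers.items()]
    )
    marker_to_class = {
        "nrv2": "glia", "VAChT": "cholinergic", "VGlut": "glutamatergic",
        "Gad1": "GABAergic",
    }
    genes = list(thr.class_markers)
    labels = np.full(len(expr), "other", dtype=object)
    one = fired.sum(axis=1) == 1
    labels[one] = [
        marker_to_class.get(genes[i], genes[i]) for i in fired[one].argmax(axis=1)
    ]
    return labels


def _stage_fuse(cfg, outdir, seed):
    adata = io.read_counts(os.path.join(outdir, "counts"))
    kept = _kept_cells(outdir)
    adata = adata[adata.obs_names.isin(kept)].copy()
    sc_qc.lognormalize(adata)
    thr = sc_qc.MarkerThresholds()
    labels = _marker_labels(adata, thr)
    # deliberately over-cluster: split each marker class in two at random,
    # then let DE-based fusion merge the indistinguishable halves back
    rng = np.random.default_rng(seed)
    split = rng.random(adata.n_obs) < 0.5
    labels = np.array(
        [f"{l}-{int(s)}" for l, s in zip(labels, split)], dtype=object
    )
    X = adata.layers["lognorm"]
    centered = X - X.mean(axis=0)
    n_pc = min(10, min(centered.shape) - 1)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    embedding = u[:, :n_pc] * s[:n_pc]
    fcfg = cluster_fusion.FusionConfig(
        min_cells_per_cluster=(cfg.get("fuse") or {}).get("min_cells_per_cluster", 3)
    )
    fused, log = cluster_fusion.fuse_clusters(
        X, adata.var_names.to_numpy(), labels, embedding, fcfg
    )
    out = pd.DataFrame({"cluster": fused}, index=adata.obs_names)
    p1 = os.path.join(outdir, "fused_labels.csv")
    p2 = os.path.join(outdir, "fusion_log.csv")
    out.to_csv(p1)
    log.to_csv(p2, index=False)
    return {p1: len(out), p2: len(log)}


def _stage_de(cfg, outdir, seed):
    adata = io.read_counts(os.path.join(outdir, "counts"))
    kept = _kept_cells(outdir)
    adata = adata[adata.obs_names.isin(kept)].copy()
    opts = cfg.get("de") or {}
    levels = set(adata.obs["condition"].unique())
    contrast = opts.get("contrast")
    if contrast is None and {"sated", "dehydrated_12h"} <= levels:
        contrast = ("dehydrated_12h", "sated")  # deprived vs control
    res = zinb_de.run_de(
        adata,
        condition_key="condition",
        contrast=tuple(contrast) if contrast else None,
        min_cells=opts.get("min_cells", 50),
        min_nonzero_cells=opts.get("min_nonzero_cells", 20),
    )
    events, per_class, genes_any = zinb_de.summarize_de(res)
    p1 = os.path.join(outdir, "de_results.csv")
    p2 = os.path.join(outdir, "de_events.csv")
    res.to_csv(p1, index=False)
    events.to_csv(p2, index=False)
    return {p1: len(res), p2: len(events)}


def _stage_calcium(cfg, outdir, seed):
    with open(os.path.join(outdir, "sim_meta.json")) as fh:
        meta = json.load(fh)
    traces = io.read_traces(
        os.path.join(outdir, "traces.csv"),
        frame_rate=meta["frame_rate"],
        onset_s=meta["onset_s"],
        offset_s=meta["offset_s"],
        drug=meta["drug"],
    )
    calls = calcium.classify_traces(traces)
    dff = calcium.compute_dff(traces.values, traces.onset_s, traces.frame_rate)
    end_s = (traces.n_frames - 1) / traces.frame_rate
    aucs = pd.DataFrame(
        {
            "cell": traces.cell_ids,
            "auc_during": [
                calcium.auc(d, traces.onset_s, traces.offset_s, traces.frame_rate,
                            normalize_at_onset=True, onset_s=traces.onset_s)
                for d in dff
            ],
            "auc_after": [
                calcium.auc(d, traces.offset_s, end_s, traces.frame_rate,
                            normalize_at_onset=True, onset_s=traces.onset_s)
                for d in dff
            ],
        }
    )
    p1 = os.path.join(outdir, "response_calls.csv")
    p2 = os.path.join(outdir, "auc.csv")
    calls.to_csv(p1, index=False)
    aucs.to_csv(p2, index=False)
    return {p1: len(calls), p2: len(aucs)}


def _stage_vicinity(cfg, outdir, seed):
    with open(os.path.join(outdir, "sim_meta.json")) as fh:
        meta = json.load(fh)
    skel = vicinity.read_swc(
        os.path.join(outdir, "skeleton.swc"), astrocyte_id=meta["astrocyte_id"]
    )
    synapses = pd.read_csv(os.path.join(outdir, "synapses.csv"))
    passing = vicinity.filter_synapses(synapses)
    fine = vicinity.fine_process_nodes(skel)
    profile = vicinity.vicinity_profile(fine, passing)
    by_count = sorted(profile.counts.items(), key=lambda kv: -kv[1])
    test = None
    if len(by_count) >= 2 and by_count[1][1] >= 10:
        (ta, _), (tb, _) = by_count[:2]
        res = vicinity.bootstrap_mean_test(
            profile.distances[ta], profile.distances[tb],
            n_boot=(cfg.get("vicinity") or {}).get("n_boot", 10000), seed=seed,
        )
        test = {
            "group_a": ta, "group_b": tb,
            "mean_a_nm": res.mean_a, "mean_b_nm": res.mean_b,
            "p": res.p, "p_raw_welch": res.p_raw_welch,
        }
    tps = vicinity.classify_tps(passing, [meta["astrocyte_id"]])
    vic_mask = np.zeros(len(passing), dtype=bool)
    vic_mask[profile.candidate_index] = True
    ratios = vicinity.transmitter_ratios(
        tps, vic_mask, passing["transmitter"].to_numpy()
    )
    p1 = os.path.join(outdir, "vicinity_profile.csv")
    p2 = os.path.join(outdir, "vicinity_test.json")
    p3 = os.path.join(outdir, "transmitter_ratios.csv")
    profile.to_frame().to_csv(p1, index=False)
    with open(p2, "w") as fh:
        json.dump(test or {}, fh)
    ratios.to_csv(p3, index=False)
    return {p1: sum(profile.counts.values()), p2: 1, p3: len(ratios)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "fuse": _stage_fuse,
    "de": _stage_de,
    "calcium": _stage_calcium,
    "vicinity": _stage_vicinity,
}


def run_pipeline(config, out_dir) -> RunManifest:
    """Execute the configured stages in order and write ``manifest.json``.

    Failure in any stage aborts the run with the stage name and cause.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=seed,
        stages=list(cfg["stages"]),
        version=__version__,
    )
    for stage in cfg["stages"]:
        try:
            files = _STAGE_FUNCS[stage](cfg, out_dir, stage_seed(seed, stage))
        except (ConfigError, DataError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise DataError(f"stage '{stage}' failed: {exc}") from exc
        manifest.files[stage] = {os.path.relpath(p, out_dir): n for p, n in files.items()}
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    return manifest
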