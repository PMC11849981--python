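"""End-to-end orchestration: preprocess -> decompose -> select-k -> analyze
-> associate -> subpop, from one configuration file.

Every stage writes its outputs plus a ``stage.json`` recording a SHA-256
hash of its parameters and upstream state; re-running an unchanged
configuration skips completed stages.  A run manifest ties every output file
to the configuration, seeds and package version, and records per-file
hashes so byte-identical reproduction can be checked.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .association import (componentwise_differential, balanced_subset,
                          fit_rf_classifier, permutation_test,
                          positionwise_differential)
from .decomposition import ChromaFactorModel, Decomposition
from .errors import ConfigError, PipelineError
from .io_preproc import (FLOAT_FMT, compute_distance_tensor,
                         filter_cells_by_missingness, impute_linear,
                         load_tensor, normalize_max, read_coordinate_table,
                         read_labels_table, save_tensor, write_labels_table)
from .kselector import evaluate_k_grid
from .subpopulation import (assign_contribution_groups, difference_map,
                            locus_pair_distances, median_distance_map)
from .template_analysis import (call_boundaries, directionality_index,
                                insulation_profile, write_track)

STAGES = ("preprocess", "decompose", "select_k", "analyze", "associate", "subpop")


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    coordinates: str
    out_dir: str
    # preprocess
    max_missing_frac: float = 0.8
    normalization: str = "per_cell_max"
    # decompose
    k: int = 20
    tol: float = 1e-4
    max_iter: int = 200
    l2_reg: float = 0.0
    # select_k (optional, informative stage)
    select_k_enabled: bool = False
    k_min: int = 2
    k_max: int = 8
    n_inits: int = 4
    # analyze
    window: int = 5
    insulation_threshold: float = 0.05
    # associate
    gene: str | None = None
    fdr_positions: float = 0.05
    fdr_components: float = 0.1
    n_perm: int = 10
    # subpop
    components: object = "auto"      # "auto" or list of ints
    quantile: float = 0.5
    anchor_bin: int | None = None
    target_bins: tuple = ()
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        """Load a TOML file with sections per stage (flat keys also accepted)."""
        raw = tomllib.loads(Path(path).read_text())
        flat = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**flat)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if not Path(self.coordinates).exists():
            raise ConfigError(f"coordinates file {self.coordinates!r} does not exist")
        if self.components == "auto" and self.gene is None:
            raise ConfigError('components="auto" requires a gene with labels')
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _param_hash(params: dict, upstream: str = "") -> str:
    payload = json.dumps(params, sort_keys=True, default=str) + upstream
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage_done(sdir: Path, phash: str) -> bool:
    meta = sdir / "stage.json"
    if not meta.exists():
        return False
    try:
        return json.loads(meta.read_text()).get("hash") == phash
    except json.JSONDecodeError:
        return False


def _finish_stage(sdir: Path, phash: str, params: dict) -> dict:
    files = {str(p.relative_to(sdir)): _sha256_file(p)
             for p in sorted(sdir.rglob("*"))
             if p.is_file() and p.name != "stage.json"}
    meta = {"hash": phash, "params": params, "files": files}
    (sdir / "stage.json").write_text(json.dumps(meta, indent=2, sort_keys=True,
                                                default=str))
    return meta


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__, "config": asdict(config),
                "stages": {}, "file_hashes": {}}
    state: dict = {}
    current_stage = None
    try:
        upstream = _sha256_file(Path(config.coordinates))
        for name in STAGES:
            current_stage = name
            runner = _STAGE_RUNNERS[name]
            enabled, params = runner.plan(config)
            if not enabled:
                manifest["stages"][name] = {"status": "disabled"}
                continue
            sdir = out / name
            sdir.mkdir(exist_ok=True)
            phash = _param_hash(params, upstream)
            if _stage_done(sdir, phash):
                runner.load(config, sdir, state)
                status = "skipped"
                meta = json.loads((sdir / "stage.json").read_text())
            else:
                runner.compute(config, sdir, state)
                meta = _finish_stage(sdir, phash, params)
                status = "complete"
            manifest["stages"][name] = {"status": status, "hash": phash,
                                        "params": params}
            for fname, fhash in meta["files"].items():
                manifest["file_hashes"][f"{name}/{fname}"] = fhash
            upstream = phash
    except Exception as exc:  # noqa: BLE001 - any stage failure is reported
        (out / "FAILED").write_text(f"{current_stage}: {exc}\n")
        if isinstance(exc, (ConfigError, PipelineError)):
            raise
        raise PipelineError(current_stage or "setup", str(exc)) from exc
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=str))
    return manifest


class _Stage:
    def __init__(self, plan, compute, load):
        self.plan = plan
        self.compute = compute
        self.load = load


# -- preprocess ---------------------------------------------------------------

def _preprocess_plan(config):
    return True, {"max_missing_frac": config.max_missing_frac,
                  "normalization": config.normalization,
                  "coordinates": str(config.coordinates)}


def _preprocess_compute(config, sdir, state):
    ensemble = read_coordinate_table(config.coordinates)
    n_input = ensemble.n
    ensemble = filter_cells_by_missingness(ensemble, config.max_missing_frac)
    ensemble = impute_linear(ensemble)
    tensor = compute_distance_tensor(ensemble)
    tensor = normalize_max(tensor, config.normalization)
    save_tensor(tensor, sdir / "tensor")
    if ensemble.labels:
        write_labels_table(ensemble.labels, ensemble.cell_ids, sdir / "labels.tsv")
    (sdir / "qc.json").write_text(json.dumps(
        {"n_input": n_input, "n_retained": ensemble.n,
         "max_missing_frac": config.max_missing_frac}, indent=2, sort_keys=True))
    state["tensor"] = tensor
    state["labels"] = dict(ensemble.labels)
    state["cell_ids"] = list(ensemble.cell_ids)


def _preprocess_load(config, sdir, state):
    tensor = load_tensor(sdir / "tensor")
    state["tensor"] = tensor
    state["cell_ids"] = list(tensor.cell_ids)
    labels_path = sdir / "labels.tsv"
    state["labels"] = (read_labels_table(labels_path, tensor.cell_ids)
                       if labels_path.exists() else {})


def _stage_files_hashes(sdir):
    meta = json.loads((sdir / "stage.json").read_text())
    return meta["files"]


# -- decompose ----------------------------------------------------------------

def _decompose_plan(config):
    return True, {"k": config.k, "tol": config.tol, "max_iter": config.max_iter,
                  "l2_reg": config.l2_reg, "seed": config.seed}


def _decompose_compute(config, sdir, state):
    model = ChromaFactorModel(state["tensor"])
    dec = model.fit(k=config.k, tol=config.tol, max_iter=config.max_iter,
                    l2_reg=config.l2_reg, seed=config.seed)
    dec.save(sdir / "model")
    # stage.json only hashes files directly in sdir; add a summary there
    (sdir / "fit.json").write_text(json.dumps(
        {"reconstruction_error": dec.reconstruction_error,
         "variance_explained": dec.variance_explained(),
         "asymmetry_norm": dec.asymmetry_norm,
         "converged": dec.solver_meta["converged"]}, indent=2, sort_keys=True))
    state["decomposition"] = dec


def _decompose_load(config, sdir, state):
    dec = Decomposition.load(sdir / "model")
    dec.model = ChromaFactorModel(state["tensor"])
    state["decomposition"] = dec


# -- select_k -----------------------------------------------------------------

def _select_k_plan(config):
    return config.select_k_enabled, {"k_min": config.k_min, "k_max": config.k_max,
                                     "n_inits": config.n_inits, "seed": config.seed,
                                     "gene": config.gene}


def _select_k_compute(config, sdir, state):
    labels = state["labels"].get(config.gene) if config.gene else None
    model = ChromaFactorModel(state["tensor"])
    report = evaluate_k_grid(model, range(config.k_min, config.k_max + 1),
                             n_inits=config.n_inits, labels=labels,
                             seed=config.seed)
    report.save(sdir)
    state["k_report"] = report


def _select_k_load(config, sdir, state):
    state["k_report"] = json.loads((sdir / "k_selection.json").read_text())


# -- analyze ------------------------------------------------------------------

def _analyze_plan(config):
    return True, {"window": config.window,
                  "insulation_threshold": config.insulation_threshold}


def _analyze_compute(config, sdir, state):
    dec = state["decomposition"]
    boundaries = {}
    for j in range(dec.k):
        template = dec.templates[:, :, j]
        ins = insulation_profile(template, config.window, source=f"template_{j}")
        di = directionality_index(template, config.window, input_kind="distance",
                                  source=f"template_{j}")
        write_track(ins, sdir / f"insulation_template_{j:03d}.tsv")
        write_track(di, sdir / f"directionality_template_{j:03d}.tsv")
        calls = call_boundaries(ins, config.insulation_threshold)
        boundaries[str(j)] = calls.positions
    (sdir / "boundaries.json").write_text(json.dumps(
        {"threshold": config.insulation_threshold, "window": config.window,
         "boundaries": boundaries}, indent=2, sort_keys=True))


def _analyze_load(config, sdir, state):
    pass


# -- associate ----------------------------------------------------------------

def _associate_plan(config):
    enabled = config.gene is not None
    return enabled, {"gene": config.gene, "fdr_positions": config.fdr_positions,
                     "fdr_components": config.fdr_components,
                     "n_perm": config.n_perm, "seed": config.seed}


def _associate_compute(config, sdir, state):
    labels = state["labels"].get(config.gene)
    if labels is None:
        raise ConfigError(f"no labels found for gene {config.gene!r}")
    dec = state["decomposition"]
    comp = componentwise_differential(dec.weights, labels,
                                      threshold=config.fdr_components)
    posn = positionwise_differential(state["tensor"], labels,
                                     threshold=config.fdr_positions)
    np.savetxt(sdir / "positionwise_q.tsv", posn.q_fdr, fmt=FLOAT_FMT,
               delimiter="\t")
    np.savetxt(sdir / "positionwise_significant.tsv",
               posn.significant.astype(int), fmt="%d", delimiter="\t")
    comp_table = {
        "component": list(range(dec.k)),
        "U": comp.statistic.tolist(),
        "p": comp.p_raw.tolist(),
        "q": comp.q_fdr.tolist(),
        "significant": comp.significant.astype(bool).tolist(),
    }
    (sdir / "componentwise.json").write_text(json.dumps(
        comp_table, indent=2, sort_keys=True))

    idx = balanced_subset(labels, seed=config.seed)
    features = dec.weights.T[idx]
    report = fit_rf_classifier(features, np.asarray(labels)[idx],
                               seed=config.seed)
    null = permutation_test(features, np.asarray(labels)[idx],
                            n_perm=config.n_perm, seed=config.seed)
    (sdir / "classifier.json").write_text(json.dumps(
        {"accuracy": report.accuracy,
         "feature_importances": report.feature_importances.tolist(),
         "permutation": {"mean": null.mean, "sd": null.sd,
                         "p_value": null.p_value,
                         "null_accuracies": list(null.null_accuracies)},
         "caveats": list(report.caveats)}, indent=2, sort_keys=True))
    state["significant_components"] = [int(c) for c in
                                       np.flatnonzero(comp.significant)]


def _associate_load(config, sdir, state):
    table = json.loads((sdir / "componentwise.json").read_text())
    state["significant_components"] = [c for c, sig in
                                       zip(table["component"], table["significant"])
                                       if sig]


# -- subpop -------------------------------------------------------------------

def _subpop_plan(config):
    enabled = config.gene is not None
    comps = config.components
    if comps != "auto":
        comps = sorted(int(c) for c in comps)
    return enabled, {"components": comps, "quantile": config.quantile,
                     "anchor_bin": config.anchor_bin,
                     "target_bins": sorted(int(t) for t in config.target_bins)}


def _subpop_compute(config, sdir, state):
    labels = state["labels"].get(config.gene)
    if config.components == "auto":
        comps = state.get("significant_components", [])
    else:
        comps = [int(c) for c in config.components]
    if not comps:
        (sdir / "groups.json").write_text(json.dumps(
            {"components_used": [], "note": "no significant components"},
            indent=2, sort_keys=True))
        return
    dec = state["decomposition"]
    tensor = state["tensor"]
    groups = assign_contribution_groups(dec.weights, labels, comps,
                                        quantile=config.quantile)
    cell_ids = state["cell_ids"]
    lines = ["cell_id\tgroup"]
    for i in groups.high_indices:
        lines.append(f"{cell_ids[i]}\thigh")
    for i in groups.low_indices:
        lines.append(f"{cell_ids[i]}\tlow")
    (sdir / "groups.tsv").write_text("\n".join(lines) + "\n")
    high_map = median_distance_map(tensor, groups.high_indices)
    low_map = median_distance_map(tensor, groups.low_indices)
    np.savetxt(sdir / "median_map_high.tsv", high_map, fmt=FLOAT_FMT, delimiter="\t")
    np.savetxt(sdir / "median_map_low.tsv", low_map, fmt=FLOAT_FMT, delimiter="\t")
    np.savetxt(sdir / "difference_map.tsv", difference_map(high_map, low_map),
               fmt=FLOAT_FMT, delimiter="\t")
    summary = {"components_used": list(groups.components_used),
               "n_high": int(groups.high_indices.size),
               "n_low": int(groups.low_indices.size),
               "fraction_of_population": groups.fraction_of_population}
    if config.anchor_bin is not None and config.target_bins:
        _, mean_high = locus_pair_distances(tensor, config.anchor_bin,
                                            config.target_bins, groups.high_indices)
        _, mean_low = locus_pair_distances(tensor, config.anchor_bin,
                                           config.target_bins, groups.low_indices)
        summary["anchor_target_mean_high"] = mean_high
        summary["anchor_target_mean_low"] = mean_low
    (sdir / "groups.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def _subpop_load(config, sdir, state):
    pass


_STAGE_RUNNERS = {
    "preprocess": _Stage(_preprocess_plan, _preprocess_compute, _preprocess_load),
    "decompose": _Stage(_decompose_plan, _decompose_compute, _decompose_load),
    "select_k": _Stage(_select_k_plan, _select_k_compute, _select_k_load),
    "analyze": _Stage(_analyze_plan, _analyze_compute, _analyze_load),
    "associate": _Stage(_associate_plan, _associate_compute, _associate_load),
    "subpop": _Stage(_subpop_plan, _subpop_compute, _subpop_load),
}
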