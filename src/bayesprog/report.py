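"""Presentation outputs and end-to-end pipeline orchestration.

The perturbation results are rendered as a predictors x (endpoint, time)
grid of log10 p-values — a compact significance heatmap with a lossless TSV
twin — and the whole pipeline (simulate-cohort -> preprocess -> learn ->
perturb -> report) can be driven from one configuration with a manifest that
records content hashes for resumable, reproducible runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import network, preprocess, simulate, synthetic  # noqa: E402
from .simulate import PerturbationResult  # noqa: E402

__all__ = ["pvalue_heatmap", "run_pipeline", "PipelineError"]

LOG10_CAP = -16.0  # display-only floor; tables keep full precision


def _column_label(result: PerturbationResult) -> str:
    t = result.time_index
    return f"{result.endpoint}@{'rate' if t == 'slope' else t}"


def pvalue_heatmap(
    results: list[PerturbationResult],
    out_dir: str | Path | None = None,
    stem: str = "pvalues",
) -> tuple[pd.DataFrame, dict[str, Path]]:
    """Assemble the log10 p-value grid; optionally render TSV + PNG.

    Rows are predictors, columns (endpoint, time-or-rate) pairs; duplicate
    cells are an error.  The TSV round-trips losslessly; the image caps values
    at 1e-16 for display only.
    """
    if not results:
        raise ValueError("no perturbation results to render")
    cells: dict[tuple[str, str], float] = {}
    for r in results:
        key = (r.predictor, _column_label(r))
        if key in cells:
            raise ValueError(f"duplicate result for {key}")
        cells[key] = np.log10(r.p_value)
    predictors = sorted({k[0] for k in cells})
    columns = sorted({k[1] for k in cells})
    grid = pd.DataFrame(np.nan, index=predictors, columns=columns)
    for (p, c), v in cells.items():
        grid.loc[p, c] = v
    grid.index.name = "predictor"
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["tsv"] = out / f"{stem}.tsv"
        grid.to_csv(paths["tsv"], sep="\t")
        fig, ax = plt.subplots(
            figsize=(1.2 + 0.6 * len(columns), 1.0 + 0.4 * len(predictors)))
        shown = grid.clip(lower=LOG10_CAP)
        im = ax.imshow(shown.to_numpy(), cmap="terrain", aspect="auto",
                       vmax=0.0, vmin=LOG10_CAP)
        ax.set_xticks(range(len(columns)), columns, rotation=45, ha="right")
        ax.set_yticks(range(len(predictors)), predictors)
        fig.colorbar(im, ax=ax, label="log10 p-value")
        fig.tight_layout()
        paths["png"] = out / f"{stem}.png"
        fig.savefig(paths["png"], dpi=120)
        plt.close(fig)
    return grid, paths


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------
class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(
            f"pipeline stage {stage!r} failed: {cause} "
            f"(fix the stage inputs and re-run; completed stages are reused)")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _signature(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Runner:
    def __init__(self, out_dir: Path):
        self.out = out_dir
        self.manifest_path = out_dir / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else {"stages": {}})

    def stage(self, name: str, signature: str, outputs: list[Path], fn):
        entry = self.manifest["stages"].get(name)
        if entry and entry["signature"] == signature and all(
                Path(p).exists() and _sha256(Path(p)) == h
                for p, h in entry["outputs"].items()):
            return  # up to date
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(name, exc) from exc
        self.manifest["stages"][name] = {
            "signature": signature,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int = 0) -> dict:
    """Execute the full study pipeline into ``out_dir``; returns the manifest.

    ``config`` is a dict (or YAML path) with optional sections ``cohort``
    (CohortConfig fields; default: the bundled demo cohort), ``learner``
    (NetworkEnsembleLearner parameters), ``perturb`` (predictors, endpoints,
    modes, n_draws, n_permutations) and ``consensus_threshold``.  Stages are
    resumed from the manifest when their inputs and outputs are unchanged.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = _Runner(out)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    # stage 1: cohort ---------------------------------------------------
    cohort_cfg = (synthetic.CohortConfig.from_dict(config["cohort"])
                  if "cohort" in config
                  else synthetic.full_demo_config(n_participants=150))
    cohort_dir = out / "cohort"
    cohort_sig = _signature({"cohort": config.get("cohort"), "seed": seeds[0]})
    cohort_files = [cohort_dir / f for f in
                    ("clinical.csv", "imaging.csv", "genotypes.tsv", "truth.csv")]
    runner.stage("cohort", cohort_sig, cohort_files,
                 lambda: synthetic.write_cohort(
                     synthetic.generate_cohort(cohort_cfg, seed=seeds[0]),
                     cohort_dir))

    # stage 2: preprocess ----------------------------------------------
    frame_path = out / "frame.csv"
    qc_path = out / "qc_report.tsv"
    pre_sig = _signature({"cohort": _sha256(cohort_files[0]),
                          "genotypes": _sha256(cohort_files[2]),
                          "seed": seeds[1]})

    def _preprocess():
        raw = synthetic.generate_cohort(cohort_cfg, seed=seeds[0])
        frame, qc = preprocess.preprocess_cohort(raw, seed=seeds[1])
        frame.to_csv(frame_path)
        qc.to_tsv(qc_path)

    runner.stage("preprocess", pre_sig, [frame_path, qc_path], _preprocess)

    # stage 3: learn ----------------------------------------------------
    learner_params = dict(config.get("learner", {}))
    learner_params.setdefault("n_networks", 128)
    learner_params.setdefault("cap", 4)
    ens_path = out / "ensemble.json"
    trace_path = out / "trace.csv"
    cons_path = out / "consensus.tsv"
    diag_path = out / "diagnostics.json"
    learn_sig = _signature({"frame": _sha256(frame_path),
                            "learner": learner_params, "seed": seeds[2]})

    def _learn():
        frame = preprocess.CohortFrame.from_csv(frame_path)
        learner = network.NetworkEnsembleLearner(
            random_state=seeds[2], **learner_params).fit(frame)
        learner.ensemble_.to_json(ens_path)
        pd.DataFrame({"total_score": learner.trace_}).to_csv(trace_path,
                                                             index=False)
        threshold = config.get("consensus_threshold", 0.30)
        network.write_consensus(learner.consensus(threshold), out)
        learner.consensus(threshold).to_csv(cons_path, sep="\t", index=False)
        diag_path.write_text(json.dumps(learner.diagnostics(), indent=1))

    runner.stage("learn", learn_sig,
                 [ens_path, trace_path, cons_path, diag_path], _learn)

    # stage 4: perturb --------------------------------------------------
    perturb_cfg = dict(config.get("perturb", {}))
    results_path = out / "perturbations.tsv"
    perturb_sig = _signature({"ensemble": _sha256(ens_path),
                              "perturb": perturb_cfg, "seed": seeds[3]})

    def _perturb():
        frame = preprocess.CohortFrame.from_csv(frame_path)
        ensemble = network.NetworkEnsemble.from_json(ens_path)
        results = run_perturbations(ensemble, frame, perturb_cfg, seeds[3])
        rows = [{"predictor": r.predictor, "endpoint": r.endpoint,
                 "time": r.time_index, "effect": r.effect, "p": r.p_value,
                 "label": r.label} for r in results]
        pd.DataFrame(rows).to_csv(results_path, sep="\t", index=False)
        out.joinpath("perturbations.json").write_text(json.dumps(
            [{"predictor": r.predictor, "endpoint": r.endpoint,
              "time": str(r.time_index), "p": r.p_value} for r in results]))
        run_perturbations.cache = results  # reused by the report stage

    runner.stage("perturb", perturb_sig, [results_path], _perturb)

    # stage 5: report ---------------------------------------------------
    grid_path = out / "pvalues.tsv"
    png_path = out / "pvalues.png"
    report_sig = _signature({"results": _sha256(results_path)})

    def _report():
        frame = preprocess.CohortFrame.from_csv(frame_path)
        results = getattr(run_perturbations, "cache", None)
        if results is None:
            ensemble = network.NetworkEnsemble.from_json(ens_path)
            results = run_perturbations(ensemble, frame, perturb_cfg, seeds[3])
        pvalue_heatmap(results, out_dir=out)

    runner.stage("report", report_sig, [grid_path, png_path], _report)
    return runner.manifest


def run_perturbations(ensemble, frame, cfg: dict, seed: int):
    predictors = cfg.get("predictors", "all-baseline")
    if predictors == "all-baseline":
        predictors = frame.columns_with_role("baseline") + sorted(
            set(frame.snp_group.values()))
    endpoints = cfg.get("endpoints")
    if endpoints is None:
        endpoints = sorted({c.split("@")[0] for c in frame.dependent_columns()})
    modes = cfg.get("modes", ["state", "progression"])
    n_perm = int(cfg.get("n_permutations", 10_000))
    n_draws = cfg.get("n_draws")
    results = []
    ss = np.random.SeedSequence(seed)
    for i, pred in enumerate(predictors):
        for endpoint in endpoints:
            times = frame.times_of(endpoint)
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            if "state" in modes:
                for t in times:
                    results.append(simulate.disease_state_perturbation(
                        ensemble, frame, pred, f"{endpoint}@{t}",
                        n_draws=n_draws, n_permutations=n_perm,
                        seed=sub_seed + t))
            if "progression" in modes and len(times) >= 3:
                res, _ = simulate.progression_perturbation(
                    ensemble, frame, pred, endpoint, n_draws=n_draws,
                    n_permutations=n_perm, seed=sub_seed)
                results.append(res)
    return results
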