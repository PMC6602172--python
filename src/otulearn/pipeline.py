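"""End-to-end workflow: preprocess -> train -> select -> compare -> design.

:func:`run_pipeline` executes the full analysis from a single config
mapping (or YAML file): load or simulate a community table, replicate-aware
split, standardization, NN and RF training and test metrics, bootstrap
feature rankings, indicator analysis, consensus selection with the Monte
Carlo overlap null, and optionally the repeated-split experiment, the
sample-size sensitivity analysis and gradient community design. Every stage
writes a flat TSV/CSV artifact and the run ends with a JSON manifest
recording the config snapshot, per-stage seeds, input checksums, package
version, stage outputs and timings — enough to reproduce the run.

Stages can be re-run in isolation: when the in-memory state lacks an
upstream product the pipeline reloads it from the cached stage output in
``outdir`` (verified against the manifest checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import (
    consensus_table,
    mc_overlap_null,
    overlap_curve,
    sign_agreement,
    top_k_sets,
)
from .data_io import (
    OtuTable,
    TargetVector,
    group_split,
    read_table,
    standardize,
    write_table,
)
from .design import (
    default_alpha_grid,
    gradient_trajectory,
    random_trajectory,
    select_extremes,
)
from .evaluation import (
    error_correlation,
    mse,
    pearson_r,
    permutation_experiment,
    sample_size_sensitivity,
)
from .indicators import (
    binarize_target,
    indicator_ordering,
    permutation_confidence,
    results_to_frame,
    significant_taxa,
)
from .nn import (
    NNTrainConfig,
    bootstrap_importance,
    predict_nn,
    random_search,
    train_nn,
)
from .rf import ForestConfig, bootstrap_rf_ranking, predict_rf, train_rf

logger = logging.getLogger("otulearn")

__all__ = ["RunManifest", "run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = (
    "data",
    "split",
    "train_nn",
    "train_rf",
    "rank_nn",
    "rank_rf",
    "indval",
    "consensus",
)
OPTIONAL_STAGES = ("permutation", "sensitivity", "design")


@dataclass
class RunManifest:
    """Reproducibility record written at the end of a run."""

    config: dict
    version: str
    seeds: dict[str, int] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class _Runner:
    def __init__(self, config: dict, outdir: Path):
        self.cfg = config
        self.out = outdir
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.manifest = RunManifest(config=config, version=__version__)
        self.state: dict = {}

    # -- helpers ----------------------------------------------------------
    def _write(self, name: str, df: pd.DataFrame) -> Path:
        path = self.out / name
        df.to_csv(path, sep="\t", index=False)
        self.manifest.outputs[name] = str(path)
        return path

    def _need_split(self):
        if "train" in self.state:
            return
        tr = self.out / "train.csv"
        te = self.out / "test.csv"
        if not (tr.exists() and te.exists()):
            raise FileNotFoundError(
                "split outputs not found; run the 'split' stage first"
            )
        self.state["train"] = read_table(tr)
        self.state["test"] = read_table(te)
        self._standardize()

    def _standardize(self):
        tr_t, tr_y = self.state["train"]
        te_t, te_y = self.state["test"]
        (tr_s, te_s), stats = standardize(tr_t, [te_t])
        self.state["scaled"] = (tr_s, te_s)
        self.state["stats"] = stats

    def _nn_config(self) -> NNTrainConfig:
        return NNTrainConfig(**self.cfg.get("nn", {}))

    def _rf_config(self) -> ForestConfig:
        return ForestConfig(**self.cfg.get("rf", {}))

    # -- stages -----------------------------------------------------------
    def stage_data(self):
        if "table" in self.cfg:
            path = Path(self.cfg["table"])
            if not path.exists():
                raise FileNotFoundError(f"input table not found: {path}")
            self.manifest.input_checksums[str(path)] = _sha256(path)
            table, target = read_table(path, **self.cfg.get("read", {}))
            if target is None:
                raise ValueError(f"no target column found in {path}")
        elif "simulate" in self.cfg:
            from .synthetic import SyntheticSpec, generate

            spec = SyntheticSpec(
                **{"seed": _stage_seed(self.seed, "simulate"),
                   **self.cfg["simulate"]}
            )
            table, target, truth = generate(spec)
            self.state["truth"] = truth
            pd.DataFrame(
                {"taxon_id": truth.taxon_ids, "effect": truth.effects}
            ).pipe(lambda df: self._write("ground_truth.tsv", df))
        else:
            raise ValueError("config needs either 'table' or 'simulate'")
        self.state["data"] = (table, target)

    def stage_split(self):
        if "data" not in self.state:
            self.stage_data()
        table, target = self.state["data"]
        seed = _stage_seed(self.seed, "split")
        self.manifest.seeds["split"] = seed
        train, test = group_split(
            table, target, float(self.cfg.get("test_fraction", 51 / 308)), seed
        )
        self.state["train"], self.state["test"] = train, test
        write_table(train[0], self.out / "train.csv", target=train[1])
        write_table(test[0], self.out / "test.csv", target=test[1])
        self.manifest.outputs["train.csv"] = str(self.out / "train.csv")
        self.manifest.outputs["test.csv"] = str(self.out / "test.csv")
        self._standardize()

    def stage_train_nn(self):
        self._need_split()
        tr_s, te_s = self.state["scaled"]
        tr_y = self.state["train"][1]
        te_y = self.state["test"][1]
        seed = _stage_seed(self.seed, "train_nn")
        self.manifest.seeds["train_nn"] = seed
        cfg = self._nn_config()
        if self.cfg.get("hyperopt", False):
            cfg = random_search(
                tr_s.counts, tr_y.values,
                n_draws=int(self.cfg.get("hyperopt_draws", 25)),
                seed=seed, groups=tr_s.group_ids, base_config=cfg,
            )
        cfg.seed = seed
        params = train_nn(tr_s.counts, tr_y.values, cfg, groups=tr_s.group_ids)
        self.state["nn"] = (params, cfg)
        self._record_metrics("nn", predict_nn(params, tr_s.counts),
                             predict_nn(params, te_s.counts))

    def stage_train_rf(self):
        self._need_split()
        tr_s, te_s = self.state["scaled"]
        tr_y = self.state["train"][1]
        seed = _stage_seed(self.seed, "train_rf")
        self.manifest.seeds["train_rf"] = seed
        cfg = self._rf_config()
        cfg.seed = seed
        forest = train_rf(tr_s.counts, tr_y.values, cfg)
        self.state["rf"] = (forest, cfg)
        self._record_metrics("rf", predict_rf(forest, tr_s.counts),
                             predict_rf(forest, te_s.counts))

    def _record_metrics(self, model, pred_train, pred_test):
        tr_y = self.state["train"][1].values
        te_y = self.state["test"][1].values
        rows = self.state.setdefault("metrics", [])
        rows.append(
            {
                "model": model,
                "train_r": pearson_r(tr_y, pred_train),
                "test_r": pearson_r(te_y, pred_test),
                "train_mse": mse(tr_y, pred_train),
                "test_mse": mse(te_y, pred_test),
            }
        )
        self.state.setdefault("test_errors", {})[model] = pred_test - te_y
        df = pd.DataFrame(rows)
        errs = self.state["test_errors"]
        if {"nn", "rf"} <= errs.keys():
            df.attrs["error_correlation"] = error_correlation(
                errs["nn"], errs["rf"]
            )
            ec = pd.DataFrame(
                [{"metric": "nn_rf_error_correlation",
                  "value": df.attrs["error_correlation"]}]
            )
            self._write("error_correlation.tsv", ec)
        self._write("metrics.tsv", df)

    def stage_rank_nn(self):
        self._need_split()
        if "nn" not in self.state:
            self.stage_train_nn()
        tr_s, _ = self.state["scaled"]
        tr_y = self.state["train"][1]
        seed = _stage_seed(self.seed, "rank_nn")
        self.manifest.seeds["rank_nn"] = seed
        boot = self.cfg.get("bootstrap", {})
        ranking = bootstrap_importance(
            tr_s.counts, tr_y.values, tr_s.taxon_ids,
            base_config=self.state["nn"][1],
            n_boot=int(boot.get("n_boot", 50)),
            subsample_fraction=float(boot.get("subsample_fraction", 0.8)),
            seed=seed, groups=tr_s.group_ids,
        )
        self.state["nn_ranking"] = ranking
        self._write("nn_importance.tsv", ranking.to_frame())

    def stage_rank_rf(self):
        self._need_split()
        tr_s, _ = self.state["scaled"]
        tr_y = self.state["train"][1]
        seed = _stage_seed(self.seed, "rank_rf")
        self.manifest.seeds["rank_rf"] = seed
        boot = self.cfg.get("bootstrap", {})
        ranking = bootstrap_rf_ranking(
            tr_s.counts, tr_y.values, tr_s.taxon_ids,
            config=self._rf_config(),
            n_boot=int(boot.get("n_boot", 50)),
            subsample_fraction=float(boot.get("subsample_fraction", 0.8)),
            seed=seed,
        )
        self.state["rf_ranking"] = ranking
        self._write("rf_importance.tsv", ranking.to_frame())

    def stage_indval(self):
        self._need_split()
        tr_t, tr_y = self.state["train"]
        seed = _stage_seed(self.seed, "indval")
        self.manifest.seeds["indval"] = seed
        iv_cfg = self.cfg.get("indval", {})
        labels = binarize_target(tr_y, iv_cfg.get("rule", "median"))
        results = permutation_confidence(
            tr_t, labels,
            n_perm=int(iv_cfg.get("n_perm", 1000)), seed=seed,
        )
        self.state["indicator_results"] = results
        self._write("indval.tsv", results_to_frame(results))

    def stage_consensus(self):
        for dep, fn in (
            ("nn_ranking", self.stage_rank_nn),
            ("rf_ranking", self.stage_rank_rf),
            ("indicator_results", self.stage_indval),
        ):
            if dep not in self.state:
                fn()
        nn_r = self.state["nn_ranking"]
        rf_r = self.state["rf_ranking"]
        iv = self.state["indicator_results"]
        k = self.cfg.get("consensus_k")  # None -> size of indicator set
        table = consensus_table(nn_r, rf_r, iv, k)
        self._write("consensus.tsv", table)
        nn_set, rf_set, ind_set = top_k_sets(nn_r, rf_r, iv, k)
        k_eff = len(ind_set) if k is None else int(k)
        curve = overlap_curve(
            nn_r.ordered_taxa(), rf_r.ordered_taxa(), indicator_ordering(iv),
            k_max=k_eff,
        )
        self._write("overlap_curve.tsv", curve.reset_index())
        seed = _stage_seed(self.seed, "mc_null")
        self.manifest.seeds["mc_null"] = seed
        null = mc_overlap_null(
            M_total=len(nn_r.taxon_ids), k_max=k_eff,
            n_sim=int(self.cfg.get("mc_sims", 1000)), seed=seed,
        )
        self._write(
            "mc_null.tsv",
            pd.DataFrame(
                {"k": null.k, "triple_mean": null.triple_mean,
                 "triple_lo": null.triple_lo, "triple_hi": null.triple_hi,
                 "pairwise_mean": null.pairwise_mean},
            ),
        )
        frac, table_sa = sign_agreement(nn_r, iv, k_eff)
        self._write("sign_agreement.tsv", table_sa)
        summary = pd.DataFrame(
            [
                {"quantity": "n_significant_indicators", "value": len(ind_set)},
                {"quantity": "nn_rf_overlap", "value": len(nn_set & rf_set)},
                {"quantity": "consensus_size",
                 "value": len(nn_set & rf_set & ind_set)},
                {"quantity": "sign_agreement", "value": frac},
            ]
        )
        self._write("consensus_summary.tsv", summary)
        self.state["consensus"] = {
            "sets": (nn_set, rf_set, ind_set),
            "summary": summary,
        }

    def stage_permutation(self):
        self._need_split()
        table, target = self.state.get("data", (None, None))
        if table is None:
            # reconstruct the full table from the split partitions
            tr_t, tr_y = self.state["train"]
            te_t, te_y = self.state["test"]
            table = OtuTable(
                sample_ids=tr_t.sample_ids + te_t.sample_ids,
                taxon_ids=tr_t.taxon_ids,
                counts=np.vstack([tr_t.counts, te_t.counts]),
                group_ids=(tr_t.group_ids or []) + (te_t.group_ids or []),
            )
            target = TargetVector(
                np.concatenate([tr_y.values, te_y.values])
            )
        cfg = self.cfg.get("permutation", {})
        reduced = cfg.get("reduced_set")
        if reduced is None and "consensus" in self.state:
            nn_set, rf_set, ind_set = self.state["consensus"]["sets"]
            reduced = sorted(nn_set & rf_set & ind_set)
        seed = _stage_seed(self.seed, "permutation")
        self.manifest.seeds["permutation"] = seed
        arms = tuple(cfg.get(
            "arms",
            ("nn_full", "nn_reduced", "rf_full", "rf_reduced")
            if reduced else ("nn_full", "rf_full"),
        ))
        result = permutation_experiment(
            table, target, reduced_set=reduced,
            n_perm=int(cfg.get("n_perm", 50)),
            test_fraction=float(self.cfg.get("test_fraction", 51 / 308)),
            arms=arms, nn_config=self._nn_config(),
            rf_config=self._rf_config(), seed=seed,
        )
        self.state["permutation"] = result
        self._write("permutation.tsv", result.records)
        self._write("permutation_summary.tsv", result.summary())

    def stage_sensitivity(self):
        self._need_split()
        cfg = self.cfg.get("sensitivity", {})
        seed = _stage_seed(self.seed, "sensitivity")
        self.manifest.seeds["sensitivity"] = seed
        fractions = cfg.get("fractions")
        if fractions is None:
            n_train = self.state["train"][0].n_samples
            fractions = [
                round(f, 2)
                for f in np.arange(0.1, 1.01, 0.1)
                if f * n_train >= 10  # smallest feasible subset
            ]
        model = cfg.get("model", "rf")
        nn_cfg, rf_cfg = self._nn_config(), self._rf_config()

        def fit_predict(Xtr, ytr, Xte, s, groups):
            if model == "nn":
                from dataclasses import replace as _rep

                return predict_nn(
                    train_nn(Xtr, ytr, _rep(nn_cfg, seed=s), groups=groups), Xte
                )
            from dataclasses import replace as _rep

            return predict_rf(train_rf(Xtr, ytr, _rep(rf_cfg, seed=s)), Xte)

        df = sample_size_sensitivity(
            self.state["train"], self.state["test"], fractions, fit_predict,
            n_rep=int(cfg.get("n_rep", 10)), seed=seed,
        )
        self.state["sensitivity"] = df
        self._write("sensitivity.tsv", df)

    def stage_design(self):
        self._need_split()
        if "nn" not in self.state:
            self.stage_train_nn()
        if "rf" not in self.state:
            self.stage_train_rf()
        if "nn_ranking" not in self.state:
            self.stage_rank_nn()
        cfg = self.cfg.get("design", {})
        seed = _stage_seed(self.seed, "design")
        self.manifest.seeds["design"] = seed
        tr_s, _ = self.state["scaled"]
        tr_y = self.state["train"][1]
        s = self.state["nn_ranking"].mean_importance
        alphas = default_alpha_grid(
            tr_s.counts, s, n_points=int(cfg.get("n_alphas", 21))
        )
        models = {"nn": self.state["nn"][0], "rf": self.state["rf"][0]}
        i_max, i_min = select_extremes(tr_y)
        frames = []
        for label, idx in (("max_target", i_max), ("min_target", i_min)):
            x0 = tr_s.counts[idx]
            g = gradient_trajectory(x0, s, alphas, models)
            g["start"], g["direction"] = label, "gradient"
            r = random_trajectory(
                x0, alphas, models, s,
                n_baselines=int(cfg.get("n_baselines", 20)), seed=seed,
            )
            r["start"] = label
            r["direction"] = "random" + r.pop("direction").astype(str)
            frames.append(g)
            frames.append(r)
        df = pd.concat(frames, ignore_index=True)
        self.state["design"] = df
        self._write("design.tsv", df)


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path | None = None,
    stages: tuple[str, ...] | None = None,
) -> RunManifest:
    """Run the workflow described by ``config`` and return the manifest.

    ``config`` is a mapping or a YAML file path. ``stages`` defaults to the
    core analysis (data through consensus); the optional ``permutation``,
    ``sensitivity`` and ``design`` stages run when listed in the config key
    ``stages`` or in the argument.
    """
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    stages = tuple(stages or config.get("stages", DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES) - set(OPTIONAL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(outdir or config.get("outdir", "otulearn_run"))
    runner = _Runner(config, outdir)
    for stage in stages:
        fn = getattr(runner, f"stage_{stage}")
        t0 = time.perf_counter()
        logger.info("stage %s ...", stage)
        try:
            fn()
        except Exception as exc:
            runner.manifest.save(outdir / "manifest.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        runner.manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage,
                    runner.manifest.timings[stage])
    runner.manifest.save(outdir / "manifest.json")
    return runner.manifest
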