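"""Cohort CSV round-tripping, run configuration and the pipeline driver.

The on-disk cohort format is a plain CSV — ``subject_id``, the three
covariates, ``roi_*`` / ``snp_*`` feature columns and ``label`` — with an
optional JSON sidecar carrying the generating spec, the planted truth and
an explicit feature-kind map (sidecar kinds override column-name
inference).  SNP columns are validated against the {0, 0.5, 1} genotype
coding on read.

``run_pipeline`` chains the stages — simulate, preprocess, train,
evaluate, explain, counterfactual-frequency, unify — from one
:class:`RunConfig`; every artifact is stamped with the master seed and a
hash of the configuration, and each stage emits one structured log record.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._common import ContractError, child_seed
from .attribution import global_shapley_ranking
from .cohort import Cohort, CohortSpec, PlantedFeature, default_cohort_spec, generate_cohort
from .counterfactual import DiverseCF, PermuteAttack
from .ensemble import fit_pair_model, nested_cv, train_test_split_eval
from .preprocess import apply_residualize_zscore, fit_residualizer
from .unify import cf_frequency_attribution, necsuff_report

__all__ = [
    "RunConfig",
    "write_cohort_csv",
    "read_cohort_csv",
    "run_pipeline",
]

logger = logging.getLogger("necsuff")

_COV_COLS = ("age", "sex", "brain_volume")
SNP_VALUES = {0.0, 0.5, 1.0}


def write_cohort_csv(cohort: Cohort, path: str | Path, sidecar: bool = True) -> Path:
    """Write a cohort as CSV (+ JSON sidecar with spec, truth and kinds)."""
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    if sidecar:
        meta = {
            "feature_kinds": dict(zip(cohort.feature_names, cohort.feature_kinds)),
            "truth": [asdict(t) for t in cohort.truth],
            "spec": _spec_dict(cohort.spec) if cohort.spec is not None else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def _spec_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["n_per_class"] = list(spec.n_per_class)
    d["planted_roi"] = {str(k): v for k, v in spec.planted_roi.items()}
    d["planted_snp"] = {str(k): v for k, v in spec.planted_snp.items()}
    if isinstance(spec.covariate_effects, Mapping):
        d["covariate_effects"] = {
            str(k): list(v) for k, v in spec.covariate_effects.items()
        }
    else:
        d["covariate_effects"] = list(spec.covariate_effects)
    return d


def read_cohort_csv(path: str | Path, sidecar: str | Path | None = None) -> Cohort:
    """Read a cohort CSV, validating SNP coding and completeness.

    Feature kinds come from the column-name prefix (``roi_`` / ``snp_``);
    a sidecar JSON (``<path>.json`` if present, or an explicit path)
    overrides the inference and restores the planted truth.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "label", *_COV_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"cohort CSV missing columns: {sorted(missing)}")

    feat_cols = [
        c for c in df.columns if c not in required
    ]
    kinds = {
        c: ("snp" if c.startswith("snp_") else "roi") for c in feat_cols
    }
    truth: list[PlantedFeature] = []
    side = Path(sidecar) if sidecar else path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
        kinds.update(
            {c: k for c, k in meta.get("feature_kinds", {}).items() if c in kinds}
        )
        truth = [PlantedFeature(**t) for t in meta.get("truth", [])]

    if df[feat_cols + list(_COV_COLS)].isna().any().any():
        na = df.columns[df.isna().any()].tolist()
        raise ContractError(f"missing values in columns {na}")
    for c in feat_cols:
        if kinds[c] == "snp":
            bad = ~df[c].isin(sorted(SNP_VALUES))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ContractError(
                    f"SNP column {c!r} row {row}: value {df[c].iloc[row]!r} "
                    "not in {0, 0.5, 1}"
                )
    return Cohort(
        features=df[feat_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=str),
        covariates=df[list(_COV_COLS)].reset_index(drop=True),
        feature_names=feat_cols,
        feature_kinds=[kinds[c] for c in feat_cols],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (one file drives everything)."""

    out_dir: str = "necsuff_run"
    cohort_csv: str | None = None  # if None, simulate
    cohort_scale: float = 0.15  # scale of the reference cohort when simulating
    control_label: str = "CN"
    scheme: str = "bagged-ovo"
    learner: str = "logistic"  # logistic | random-forest | gradient-boosting | svm | mlp
    grid: dict = field(default_factory=dict)
    cv: str = "tts"  # tts | nested
    pair: tuple[str, str] = ("MCI", "AD")
    positive: str = "AD"
    top_k: int = 5
    generators: tuple[str, ...] = ("permute", "diverse")
    n_explain: int = 20  # instances explained / unified
    shapley_samples: int = 50
    cf_budget: int = 1500
    budgets: tuple[int, ...] = (1, 2, 4, 8)
    seed: int = 0
    label_column: str = "label"
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.label_column != "label":
            raise ContractError(
                "cohort CSVs use the fixed label column name 'label'; "
                f"got {self.label_column!r}"
            )
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise ContractError(f"cohort_csv not found: {self.cohort_csv}")
        unknown = set(self.generators) - {"permute", "diverse"}
        if unknown:
            raise ContractError(f"unknown generators: {sorted(unknown)}")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths/verbosity excluded)."""
        d = {k: v for k, v in asdict(self).items()
             if k not in ("out_dir", "verbosity")}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def make_learner(name: str, seed: int = 0):
    """Instantiate a probabilistic base learner by short name."""
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    learners = {
        "logistic": lambda: LogisticRegression(max_iter=2000),
        "random-forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "gradient-boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "svm": lambda: SVC(probability=True, random_state=seed),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=800, random_state=seed
        ),
    }
    if name not in learners:
        raise ContractError(f"unknown learner {name!r}; one of {sorted(learners)}")
    return learners[name]()


def _stamp(obj: dict, config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash(), **obj}


def _emit(out_dir: Path, name: str, payload: dict, config: RunConfig) -> Path:
    p = out_dir / name
    p.write_text(json.dumps(_stamp(payload, config), indent=1, default=_jsonable))
    return p


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> preprocess -> train -> explain -> unify.

    Returns a bundle with per-stage artifacts and timings; JSON artifacts
    land in ``config.out_dir``, each stamped with seed and config hash.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    seeds = {s: child_seed(master) for s in
             ("simulate", "train", "explain", "counterfactual", "unify")}
    bundle: dict = {"stages": []}
    stage = "start"

    def log_stage(name: str, t0: float, **info):
        rec = {"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3), **info}
        logger.info(json.dumps(rec))
        bundle["stages"].append(rec)

    try:
        stage = "simulate"
        t0 = time.perf_counter()
        if config.cohort_csv:
            cohort = read_cohort_csv(config.cohort_csv)
        else:
            spec = default_cohort_spec(seed=seeds["simulate"],
                                       scale=config.cohort_scale)
            cohort = generate_cohort(spec)
            write_cohort_csv(cohort, out_dir / "cohort.csv")
        log_stage(stage, t0, n_subjects=cohort.n_subjects)

        stage = "preprocess"
        t0 = time.perf_counter()
        model_res = fit_residualizer(cohort, config.control_label)
        cohort_z = apply_residualize_zscore(model_res, cohort)
        log_stage(stage, t0, n_controls=model_res.n_controls)

        stage = "train"
        t0 = time.perf_counter()
        X, y = cohort_z.features, cohort_z.labels
        learner = make_learner(config.learner, seed=seeds["train"])
        if config.cv == "nested":
            cvres = nested_cv(X, y, learner, config.grid,
                              seed=seeds["train"], scheme=config.scheme)
            metrics = {"cv": "nested", "folds": cvres.folds, "summary": cvres.summary}
        else:
            tts = train_test_split_eval(X, y, learner, scheme=config.scheme,
                                        seed=seeds["train"])
            metrics = {k: v for k, v in tts.items() if k != "model"}
        _emit(out_dir, "metrics.json", metrics, config)
        log_stage(stage, t0, scheme=config.scheme, learner=config.learner)

        stage = "explain"
        t0 = time.perf_counter()
        pair_model = fit_pair_model(X, y, config.pair, learner,
                                    positive=config.positive)
        pair_mask = np.isin(y, sorted(config.pair))
        Xp = X[pair_mask]
        rng = np.random.default_rng(seeds["explain"])
        bg = Xp[rng.choice(len(Xp), size=min(100, len(Xp)), replace=False)]
        eval_rows = Xp[rng.choice(len(Xp), size=min(config.n_explain, len(Xp)),
                                  replace=False)]
        ranking = global_shapley_ranking(
            pair_model, bg, eval_rows, n_samples=config.shapley_samples,
            seed=seeds["explain"], feature_names=cohort.feature_names,
        )
        _emit(out_dir, "explanation.json", {
            "method": ranking.method,
            "features": [
                {"feature": cohort.feature_names[j], "value": float(ranking.values[j]),
                 "rank": r + 1}
                for r, j in enumerate(ranking.ordering)
            ],
        }, config)
        log_stage(stage, t0, top_feature=cohort.feature_names[int(ranking.top(1)[0])])

        stage = "counterfactual"
        t0 = time.perf_counter()
        gens = {}
        if "permute" in config.generators:
            gens["permute"] = PermuteAttack()
        if "diverse" in config.generators:
            gens["diverse"] = DiverseCF()
        freq = cf_frequency_attribution(
            pair_model, eval_rows, next(iter(gens.values())),
            seed=seeds["counterfactual"], reference_pool=Xp,
            feature_kinds=cohort.feature_kinds, budget=config.cf_budget,
            feature_names=cohort.feature_names,
        )
        _emit(out_dir, "cf_frequency.json", {
            "n_instances": freq.n_instances,
            "n_counterfactuals": freq.n_counterfactuals,
            "n_no_counterfactual": freq.n_no_counterfactual,
            "features": [
                {"feature": cohort.feature_names[j],
                 "fraction": float(freq.fractions[j]),
                 "direction": int(freq.directions[j])}
                for j in freq.ordering if freq.counts[j] > 0
            ],
        }, config)
        log_stage(stage, t0, n_cfs=freq.n_counterfactuals)

        stage = "unify"
        t0 = time.perf_counter()
        report = necsuff_report(
            pair_model, eval_rows, ranking, config.top_k, gens,
            seed=seeds["unify"], budgets=config.budgets, reference_pool=Xp,
            feature_kinds=cohort.feature_kinds, budget=config.cf_budget,
        )
        _emit(out_dir, "necsuff.json", {
            "n_instances": report.n_instances,
            "budgets": list(report.budgets),
            "top_features": [cohort.feature_names[j] for j in report.top_features],
            "entries": [
                {"generator": g, "target": t, **{
                    m: {str(b): v for b, v in vals[m].items()}
                    for m in ("necessity", "sufficiency_raw", "sufficiency")
                }}
                for (g, t), vals in report.entries.items()
            ],
        }, config)
        report.to_frame().to_csv(out_dir / "necsuff.csv", index=False)
        log_stage(stage, t0, n_targets=len(report.entries))
    except Exception as exc:  # noqa: BLE001 - annotate failing stage, keep artifacts
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    bundle.update(
        cohort=cohort_z, metrics=metrics, ranking=ranking,
        frequency=freq, necsuff=report, out_dir=out_dir,
    )
    return bundle
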