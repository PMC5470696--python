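"""End-to-end orchestration: featurize → select → train → predict → evaluate.

The central object is :class:`PredSAV`, a model over a labeled feature
matrix whose :meth:`~PredSAV.fit` runs the two-step feature selection and
trains the final gradient-tree-boosting classifier, returning a
:class:`PredSAVResults` that carries the stability scores, the SFS trace,
the fitted ensemble, cross-validated diagnostics and a ``summary()`` table.
:func:`run_pipeline` wraps the same flow around files on disk with full
reproducibility metadata.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from predsav.structure import ProteinStructure, read_structure
from predsav.neighborhood import BaseFeatureTable, NeighborhoodEncoder
from predsav.selection import (
    DEFAULT_CUTOFF,
    FeatureMatrix,
    StabilityScores,
    SelectionTrace,
    stability_selection,
    threshold_select,
    sequential_forward_selection,
)
from predsav.gtb import GTBResults, train_gtb, save_model
from predsav.metrics import cross_validate, evaluate_predictions

#: candidates kept when no feature clears the stability cutoff
FALLBACK_TOP_K = 20


# ---------------------------------------------------------------------------
# variant tables

VARIANT_COLUMNS = ["structure_id", "chain", "position", "wt", "mut", "label"]


def read_variants(path) -> pd.DataFrame:
    """Read a variant TSV (structure id, chain, author residue position,
    wild-type AA, mutant AA, ±1 label)."""
    df = pd.read_csv(path, sep="\t", dtype={"position": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table is missing columns: {missing}")
    return df


def encode_variant_table(
    s: ProteinStructure,
    bft: BaseFeatureTable,
    variants: pd.DataFrame,
    radius: float = 5.0,
    window: int = 11,
    euclidean_semantics: str = "neighbor_sum",
    jitter: bool = False,
):
    """Encode every variant row on one structure.

    Variants address residues by author numbering, which is translated to
    the contiguous ``seq_index``; a wild-type amino acid that disagrees with
    the structure is flagged (``wt_mismatch`` column) with a warning but
    still encoded.

    Returns ``(FeatureMatrix, annotated variants DataFrame)``.
    """
    encoder = NeighborhoodEncoder(
        s, radius=radius, window=window,
        euclidean_semantics=euclidean_semantics, jitter=jitter,
    )
    rows, names, mismatches, seq_idx = [], None, [], []
    for _, row in variants.iterrows():
        res = s.find_by_auth_number(str(row["position"]))
        mismatch = res.aa != str(row["wt"]).upper()
        if mismatch:
            warnings.warn(
                f"variant {row['wt']}{row['position']}{row['mut']}: structure "
                f"has {res.aa} at author position {row['position']}"
            )
        ev = encoder.encode(bft, res.seq_index)
        names = names or ev.names
        rows.append(ev.vector)
        mismatches.append(mismatch)
        seq_idx.append(res.seq_index)
    annotated = variants.copy()
    annotated["seq_index"] = seq_idx
    annotated["wt_mismatch"] = mismatches
    fm = FeatureMatrix(
        names=names, X=np.vstack(rows), y=variants["label"].to_numpy(dtype=int)
    )
    return fm, annotated


# ---------------------------------------------------------------------------
# the model / results pair


class PredSAV:
    """Disease-association model for encoded variants.

    Parameters
    ----------
    fm : FeatureMatrix
        Encoded variants with ±1 labels.
    cutoff : float
        Stability-selection threshold (features with score strictly above it
        enter the SFS stage; default 0.2).
    folds : int
        Cross-validation folds for both the SFS criterion and the final
        diagnostics (default 5).
    seed : int
        Master seed for subsampling, fold partitions and tree fitting.
    stability_params, sfs_params, gtb_params : dict, optional
        Overrides for the three stages (e.g. ``stability_params=
        {"n_resamples": 50}``, ``gtb_params={"n_trees": 2000, "depth": 3}``).
    """

    def __init__(
        self,
        fm: FeatureMatrix,
        cutoff: float = DEFAULT_CUTOFF,
        folds: int = 5,
        seed: int = 0,
        stability_params: dict | None = None,
        sfs_params: dict | None = None,
        gtb_params: dict | None = None,
    ):
        self.fm = fm
        self.cutoff = cutoff
        self.folds = folds
        self.seed = seed
        self.stability_params = dict(stability_params or {})
        self.sfs_params = dict(sfs_params or {})
        self.gtb_params = dict(n_trees=2000, depth=3, learning_rate=0.1)
        self.gtb_params.update(gtb_params or {})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs) -> "PredSAV":
        return cls(FeatureMatrix.from_frame(df, label_col=label_col), **kwargs)

    def fit(self, diagnostics: bool = True) -> "PredSAVResults":
        """Run stability selection, SFS and the final boosting fit.

        With ``diagnostics=False`` the (fresh-partition) cross-validation of
        the selected set is skipped; used by :func:`nested_pipeline_auc`
        where the evaluation happens outside.
        """
        stability = stability_selection(self.fm, seed=self.seed, **self.stability_params)
        candidates = threshold_select(stability, cutoff=self.cutoff)
        fallback_used = False
        if not candidates:
            # keep the pipeline usable on signal-free data: take the best-
            # scoring features instead of an empty candidate set
            fallback_used = True
            order = np.argsort(-stability.scores, kind="stable")
            candidates = [stability.names[i] for i in order[:FALLBACK_TOP_K]]
        trace = sequential_forward_selection(
            self.fm,
            candidates,
            folds=self.folds,
            seed=self.seed,
            stability=stability,
            **self.sfs_params,
        )
        sub = self.fm.subset(trace.selected)
        model = train_gtb(sub, seed=self.seed, **self.gtb_params)
        cv = None
        if diagnostics:
            # a fresh fold partition (seed+1) so the reported CV is not the
            # one the SFS criterion optimized; note that the features were
            # still selected on the full data, so this estimate is optimistic
            # when no real signal exists (see nested_pipeline_auc)
            cv = cross_validate(
                sub,
                learner_config=self.gtb_params,
                folds=self.folds,
                seed=self.seed + 1,
            )
        return PredSAVResults(
            spec=self,
            stability=stability,
            candidates=candidates,
            fallback_used=fallback_used,
            trace=trace,
            model=model,
            cv=cv,
        )


@dataclass
class PredSAVResults:
    """Fitted two-step-selection + boosting pipeline."""

    spec: PredSAV
    stability: StabilityScores
    candidates: list
    fallback_used: bool
    trace: SelectionTrace
    model: GTBResults
    cv: dict | None

    @property
    def selected_features(self) -> list:
        return list(self.trace.selected)

    def predict(self, X):
        """PredictionSet for new variants (DataFrame columns are aligned by
        the selected feature names)."""
        if isinstance(X, FeatureMatrix):
            X = X.subset(self.selected_features).X
        elif isinstance(X, pd.DataFrame):
            X = X[self.selected_features]
        return self.model.predict(X)

    def summary(self) -> str:
        if self.cv is None:
            raise ValueError("fit(diagnostics=True) required for a summary")
        mean = self.cv["mean"]
        lines = [
            "PredSAV two-step selection + gradient tree boosting",
            "===================================================",
            f"variants                : {self.spec.fm.n_samples} "
            f"({int(np.sum(self.spec.fm.y == 1))} disease / "
            f"{int(np.sum(self.spec.fm.y == -1))} neutral)",
            f"initial features        : {self.spec.fm.n_features}",
            f"stability cutoff        : {self.spec.cutoff}"
            + ("  (no feature passed; top-score fallback used)" if self.fallback_used else ""),
            f"candidates after step 1 : {len(self.candidates)}",
            f"selected after SFS      : {len(self.selected_features)} "
            f"({self.trace.stop_reason})",
            f"final model             : {self.model.n_trees} trees, "
            f"depth {self.model.depth}, lr {self.model.learning_rate}",
            "",
            f"{self.spec.folds}-fold CV (fresh partition):",
            f"  pooled AUC : {self.cv['pooled_auc']:.3f}",
            f"  mean  AUC  : {mean.AUC:.3f}   ACC : {mean.ACC:.3f}   "
            f"SEN : {mean.SEN:.3f}   SPE : {mean.SPE:.3f}",
            f"  mean  PRE  : {mean.PRE:.3f}   F1  : {mean.F1:.3f}   "
            f"MCC : {mean.MCC:.3f}",
            "",
            "selected features (SFS order, CV-AUC trace):",
        ]
        for name, auc in zip(self.trace.selected, self.trace.auc_trace):
            lines.append(f"  {name:<32s} {auc:.3f}")
        return "\n".join(lines)


def nested_pipeline_auc(fm: FeatureMatrix, folds: int = 2, seed: int = 0, **predsav_kwargs):
    """Leakage-free generalization estimate of the whole pipeline.

    Cross-validating only the *final* classifier understates the optimism of
    selecting features on the full data first: with many more features than
    variants, spuriously label-correlated features get selected and inflate
    the later CV even when the labels carry no signal.  Here the entire
    pipeline — stability selection, SFS and boosting — is re-run inside each
    training fold and only the untouched fold is scored, so the pooled
    out-of-fold AUC is unbiased (chance level on permuted labels).

    Returns ``(pooled_auc, pooled_scores)``.
    """
    from predsav.metrics import roc_auc, stratified_folds

    splits = stratified_folds(fm.y, folds=folds, seed=seed)
    pooled = np.zeros(len(fm.y))
    for k, (tr, te) in enumerate(splits):
        inner = FeatureMatrix(names=list(fm.names), X=fm.X[tr], y=fm.y[tr])
        res = PredSAV(inner, seed=seed + k, **predsav_kwargs).fit(diagnostics=False)
        test = FeatureMatrix(names=list(fm.names), X=fm.X[te], y=fm.y[te])
        pooled[te] = res.predict(test).decision
    return roc_auc(fm.y, pooled), pooled


# ---------------------------------------------------------------------------
# file-level pipeline


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serialized next to the
    outputs)."""

    out_dir: str
    pdb: str | None = None
    chain: str | None = None
    base_features: str | None = None
    variants: str | None = None
    matrix: str | None = None  # pre-encoded alternative to the four inputs above
    radius: float = 5.0
    window: int = 11
    euclidean_semantics: str = "neighbor_sum"
    jitter: bool = False
    cutoff: float = DEFAULT_CUTOFF
    folds: int = 5
    n_resamples: int = 200
    subsample_frac: float = 0.5
    weakness: float = 0.5
    selection_trees: int = 200
    trees: int = 2000
    depth: int = 3
    learning_rate: float = 0.1
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of everything that determines the results (the output
        location is excluded, so reruns into different directories match)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run featurize → select → train → predict → evaluate, writing every
    stage artifact (plus the resolved config and a log) under
    ``cfg.out_dir``.  Deterministic artifacts are bit-identical across
    reruns with the same config."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list = []
    t0 = time.time()

    def log(stage: str, msg: str):
        log_lines.append(f"[{stage}] t={time.time() - t0:.2f}s seed={cfg.seed} {msg}")

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- featurize ----------------------------------------------------------
    try:
        if cfg.matrix is not None:
            fm = FeatureMatrix.read_tsv(cfg.matrix)
            annotated = None
        else:
            if not (cfg.pdb and cfg.chain and cfg.base_features and cfg.variants):
                raise ValueError(
                    "either 'matrix' or all of pdb/chain/base_features/variants required"
                )
            s = read_structure(cfg.pdb, cfg.chain)
            bft = BaseFeatureTable.read_tsv(cfg.base_features)
            variants = read_variants(cfg.variants)
            fm, annotated = encode_variant_table(
                s, bft, variants,
                radius=cfg.radius, window=cfg.window,
                euclidean_semantics=cfg.euclidean_semantics, jitter=cfg.jitter,
            )
        fm.to_tsv(out / "encoded_matrix.tsv")
        if annotated is not None:
            annotated.to_csv(out / "variants_annotated.tsv", sep="\t", index=False)
        log("featurize", f"{fm.n_samples} variants x {fm.n_features} features")
    except Exception as e:  # noqa: BLE001 - stage failures must name the stage
        fail("featurize", e)

    # -- select + train -----------------------------------------------------
    try:
        model_spec = PredSAV(
            fm,
            cutoff=cfg.cutoff,
            folds=cfg.folds,
            seed=cfg.seed,
            stability_params=dict(
                n_resamples=cfg.n_resamples,
                subsample_frac=cfg.subsample_frac,
                weakness=cfg.weakness,
            ),
            sfs_params=dict(learner_config=dict(
                n_trees=cfg.selection_trees, depth=cfg.depth,
                learning_rate=cfg.learning_rate,
            )),
            gtb_params=dict(
                n_trees=cfg.trees, depth=cfg.depth, learning_rate=cfg.learning_rate
            ),
        )
        results = model_spec.fit()
        pd.DataFrame(
            {"feature": results.stability.names, "score": results.stability.scores}
        ).to_csv(out / "stability_scores.tsv", sep="\t", index=False)
        trace_payload = results.trace.as_dict()
        trace_payload["config_hash"] = cfg.config_hash()
        (out / "selection_trace.json").write_text(json.dumps(trace_payload, indent=2))
        save_model(results.model, out / "model.json")
        log("select", f"{len(results.candidates)} candidates -> "
            f"{len(results.selected_features)} selected")
        log("train", f"{results.model.n_trees} trees")
    except Exception as e:  # noqa: BLE001
        fail("select/train", e)

    # -- predict + evaluate -------------------------------------------------
    try:
        preds = results.predict(fm)
        pred_df = pd.DataFrame(
            {
                "label": fm.y,
                "decision": preds.decision,
                "probability": preds.probability,
                "predicted": preds.labels,
            }
        )
        pred_df.to_csv(out / "predictions.tsv", sep="\t", index=False)
        training_report = evaluate_predictions(fm.y, preds.decision)
        report = dict(
            config_hash=cfg.config_hash(),
            n_variants=fm.n_samples,
            n_features_initial=fm.n_features,
            n_candidates=len(results.candidates),
            selected_features=results.selected_features,
            cv_pooled_auc=float(results.cv["pooled_auc"]),
            cv_mean={k: float(v) for k, v in results.cv["mean"].as_dict().items()},
            cv_folds=[
                {k: float(v) for k, v in r.as_dict().items()}
                for r in results.cv["folds"]
            ],
            training={k: float(v) for k, v in training_report.as_dict().items()},
        )
        (out / "metrics.json").write_text(json.dumps(report, indent=2))
        log("evaluate", f"pooled CV AUC = {report['cv_pooled_auc']:.3f}")
    except Exception as e:  # noqa: BLE001
        fail("predict/evaluate", e)

    (out / "run_config.json").write_text(
        json.dumps({**asdict(cfg), "config_hash": cfg.config_hash()}, indent=2)
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
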