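"""Feature assembly and cross-validated ΔΔG regression.

The modelling surface follows the Model/Results idiom: build a
:class:`DdgBoostModel` from a feature table (or directly from mutation
records plus structures via :func:`build_feature_table`), then ``fit()``
for a single gradient-boosted fit or ``crossvalidate()`` for the k-fold
protocol whose pooled Pearson correlation (R_p) and RMSE (kcal/mol) are
the standard benchmark metrics for mutation-induced binding free energy
change prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .siteselect import MutationSpec
from .spectra import FeatureConfig, spectral_features
from .structio import ComplexStructure, StructureError
from .structeval import classify_regions

__all__ = [
    "MutationRecord",
    "FeatureTable",
    "DdgBoostModel",
    "DdgResults",
    "DdgCVResults",
    "pearson_r",
    "rmse",
    "build_feature_table",
    "reverse_record",
    "GBT_PARAMS",
]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
REGIONS = ("interior", "surface", "support", "rim", "core")

#: Gradient-boosted-tree settings: a deep-tree, slow-learning ensemble with
#: a generous ceiling cut short by early stopping on a 5% validation slice.
GBT_PARAMS = {
    "max_depth": 7,
    "n_estimators": 10_000,
    "learning_rate": 0.01,
    "early_stopping_rounds": 50,
    "validation_fraction": 0.05,
}


@dataclass(frozen=True)
class MutationRecord:
    """A mutation with its ΔΔG and direct/reverse orientation.

    A reverse record models the back-mutation: ΔΔG negated, wild-type and
    mutant swapped. ``reverse_record`` is an involution.
    """

    spec: MutationSpec
    ddg: float
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise ValueError("ddg must be finite")

    @property
    def pair_id(self) -> str:
        """Shared by a mutation and its reverse (fold-assignment unit)."""
        s = self.spec
        wt, mut = (s.mut, s.wt) if self.is_reverse else (s.wt, s.mut)
        return f"{s.complex_id}:{wt}{s.chain_id}{s.position}{s.icode}{mut}"


def reverse_record(record: MutationRecord) -> MutationRecord:
    s = record.spec
    return MutationRecord(
        spec=MutationSpec(
            complex_id=s.complex_id, chain_id=s.chain_id, position=s.position,
            wt=s.mut, mut=s.wt, icode=s.icode, ddg=None,
        ),
        ddg=-record.ddg,
        is_reverse=not record.is_reverse,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation R_p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length ≥ 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    from scipy.stats import pearsonr

    return float(pearsonr(x, y).statistic)


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root-mean-square error, kcal/mol for ΔΔG vectors."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or len(pred) < 1:
        raise ValueError("need equal-length non-empty vectors")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


@dataclass
class FeatureTable:
    """Row-per-record design matrix with its layout and exclusion report."""

    X: pd.DataFrame
    y: np.ndarray
    records: list[MutationRecord]
    layout: dict
    exclusions: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def complex_ids(self) -> np.ndarray:
        return np.array([r.spec.complex_id for r in self.records])

    @property
    def pair_ids(self) -> np.ndarray:
        return np.array([r.pair_id for r in self.records])

    def to_csv(self, path, layout_path=None) -> None:
        out = self.X.copy()
        out.insert(0, "ddg", self.y)
        out.insert(0, "record", [r.pair_id for r in self.records])
        out.to_csv(path, index=False, float_format="%.10g")
        if layout_path is not None:
            Path(layout_path).write_text(json.dumps(self.layout, indent=1))


def _one_hot(letter: str, alphabet: Sequence[str], prefix: str) -> pd.Series:
    return pd.Series(
        {f"{prefix}_{a}": 1.0 if a == letter else 0.0 for a in alphabet}
    )


def build_feature_table(
    records: Sequence[MutationSpec | MutationRecord],
    structures: dict[str, ComplexStructure],
    config: Optional[FeatureConfig] = None,
    include_reverse: bool = True,
    include_regions: bool = True,
    region_sphere_points: int = 240,
    embeddings: Optional[pd.DataFrame] = None,
    precomputed_spectral: Optional[pd.DataFrame] = None,
) -> FeatureTable:
    """Assemble the design matrix for ΔΔG regression.

    Each row concatenates the spectral feature blocks (computed on the
    wild-type geometry), one-hot wild-type and mutant amino acids, a
    one-hot region label of the mutated residue, and an optional external
    embedding block joined on the record's pair id. Direct and reverse
    variants of one mutation share the spectral block, mirror the one-hots
    and negate ΔΔG. Records whose structure or residue cannot be resolved
    are collected into the exclusion report, never silently dropped.
    """
    cfg = config or FeatureConfig()
    kept: list[MutationRecord] = []
    rows: list[pd.Series] = []
    exclusions: list[dict] = []
    region_cache: dict[str, dict] = {}

    base_records: list[MutationRecord] = []
    for rec in records:
        if isinstance(rec, MutationSpec):
            if rec.ddg is None:
                exclusions.append({"record": rec.label, "complex": rec.complex_id,
                                   "reason": "no ddg value"})
                continue
            rec = MutationRecord(spec=rec, ddg=rec.ddg)
        base_records.append(rec)

    for rec in base_records:
        spec = rec.spec
        structure = structures.get(spec.complex_id)
        if structure is None:
            exclusions.append({"record": spec.label, "complex": spec.complex_id,
                               "reason": "structure unavailable"})
            continue
        try:
            # Spectral features use the wild-type residue identity; a reverse
            # record's site is still the same residue in the given geometry.
            probe = spec if not rec.is_reverse else MutationSpec(
                complex_id=spec.complex_id, chain_id=spec.chain_id,
                position=spec.position, wt=spec.mut, mut=spec.wt, icode=spec.icode,
            )
            if precomputed_spectral is not None and rec.pair_id in precomputed_spectral.index:
                spectral = precomputed_spectral.loc[rec.pair_id]
            else:
                feats = spectral_features(structure, probe, cfg)
                spectral = pd.Series(feats.values, index=feats.names)
        except (StructureError, ValueError) as exc:
            exclusions.append({"record": spec.label, "complex": spec.complex_id,
                               "reason": str(exc)})
            continue

        parts = [spectral,
                 _one_hot(spec.wt, AA_LETTERS, "wt"),
                 _one_hot(spec.mut, AA_LETTERS, "mut")]
        if include_regions:
            if spec.complex_id not in region_cache:
                region_cache[spec.complex_id] = classify_regions(
                    structure, n_points=region_sphere_points
                )
            label = region_cache[spec.complex_id].get(
                (spec.chain_id, spec.position, spec.icode)
            )
            parts.append(_one_hot(label.label if label else "", REGIONS, "region"))
        if embeddings is not None:
            if rec.pair_id in embeddings.index:
                parts.append(embeddings.loc[rec.pair_id].add_prefix("emb_"))
            else:
                exclusions.append({"record": spec.label, "complex": spec.complex_id,
                                   "reason": "no embedding row"})
                continue
        rows.append(pd.concat(parts))
        kept.append(rec)

        if include_reverse and not rec.is_reverse:
            rev = reverse_record(rec)
            rev_parts = [spectral,
                         _one_hot(rev.spec.wt, AA_LETTERS, "wt"),
                         _one_hot(rev.spec.mut, AA_LETTERS, "mut")]
            if include_regions:
                rev_parts.append(parts[3])  # same residue, same region
            if embeddings is not None:
                rev_parts.append(embeddings.loc[rec.pair_id].add_prefix("emb_"))
            rows.append(pd.concat(rev_parts))
            kept.append(rev)

    X = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame()
    y = np.array([r.ddg for r in kept])
    layout = {
        "n_records": len(kept),
        "n_features": int(X.shape[1]) if len(X) else 0,
        "include_reverse": include_reverse,
        "include_regions": include_regions,
        "feature_blocks": {
            "spectral": int(sum(1 for c in X.columns if "|" in str(c))) if len(X) else 0,
            "one_hot": int(sum(str(c).startswith(("wt_", "mut_", "region_")) for c in X.columns)) if len(X) else 0,
            "embedding": int(sum(str(c).startswith("emb_") for c in X.columns)) if len(X) else 0,
        },
    }
    return FeatureTable(X=X, y=y, records=kept, layout=layout, exclusions=exclusions)


@dataclass
class DdgResults:
    """A fitted gradient-boosted ΔΔG model with training diagnostics."""

    model: object
    train_pearson_r: float
    train_rmse: float
    n_train: int
    best_iteration: Optional[int]
    feature_names: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.model.predict(X.to_numpy()))

    def summary(self) -> str:
        lines = [
            "Gradient-boosted ΔΔG regression — training fit",
            "=" * 48,
            f"{'n(train)':<28}{self.n_train:>20d}",
            f"{'boosting rounds used':<28}{self.best_iteration or 0:>20d}",
            f"{'train R_p':<28}{self.train_pearson_r:>20.3f}",
            f"{'train RMSE (kcal/mol)':<28}{self.train_rmse:>20.3f}",
        ]
        return "\n".join(lines)


@dataclass
class DdgCVResults:
    """k-fold cross-validation outcome.

    Carries per-fold R_p and RMSE, their mean ± sd, the pooled
    out-of-fold metrics, and the exact fold assignment for reproducibility.
    """

    fold_metrics: pd.DataFrame  # fold, n_test, pearson_r, rmse
    pooled_pearson_r: float
    pooled_rmse: float
    fold_assignment: np.ndarray
    predictions: np.ndarray
    observed: np.ndarray
    seed: int
    folds: int
    grouping: str

    @property
    def pearson_r_mean(self) -> float:
        return float(self.fold_metrics["pearson_r"].mean())

    @property
    def pearson_r_sd(self) -> float:
        return float(self.fold_metrics["pearson_r"].std(ddof=1))

    @property
    def rmse_mean(self) -> float:
        return float(self.fold_metrics["rmse"].mean())

    @property
    def rmse_sd(self) -> float:
        return float(self.fold_metrics["rmse"].std(ddof=1))

    def summary(self) -> str:
        lines = [
            f"{self.folds}-fold cross-validation — ΔΔG prediction",
            "=" * 52,
            f"{'records':<30}{len(self.observed):>20d}",
            f"{'fold grouping':<30}{self.grouping:>20s}",
            f"{'seed':<30}{self.seed:>20d}",
            f"{'pooled R_p':<30}{self.pooled_pearson_r:>20.3f}",
            f"{'pooled RMSE (kcal/mol)':<30}{self.pooled_rmse:>20.3f}",
            f"{'per-fold R_p':<30}{self.pearson_r_mean:>13.3f} ± {self.pearson_r_sd:.3f}",
            f"{'per-fold RMSE':<30}{self.rmse_mean:>13.3f} ± {self.rmse_sd:.3f}",
            "-" * 52,
            f"{'fold':<8}{'n_test':>8}{'R_p':>12}{'RMSE':>12}",
        ]
        for _, row in self.fold_metrics.iterrows():
            rp = row["pearson_r"]
            lines.append(
                f"{int(row['fold']):<8d}{int(row['n_test']):>8d}"
                f"{(f'{rp:.3f}' if np.isfinite(rp) else 'n/a'):>12}"
                f"{row['rmse']:>12.3f}"
            )
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Scatter of pooled out-of-fold predictions against observed ΔΔG."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(self.observed, self.predictions, s=12, alpha=0.6,
                   edgecolors="none")
        lims = [
            min(self.observed.min(), self.predictions.min()),
            max(self.observed.max(), self.predictions.max()),
        ]
        ax.plot(lims, lims, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("observed ΔΔG (kcal/mol)")
        ax.set_ylabel("predicted ΔΔG (kcal/mol)")
        ax.set_title(
            f"{self.folds}-fold CV: R_p={self.pooled_pearson_r:.2f}, "
            f"RMSE={self.pooled_rmse:.2f}"
        )
        return ax

    def to_json(self, path) -> None:
        payload = {
            "folds": self.folds,
            "seed": self.seed,
            "grouping": self.grouping,
            "pooled_pearson_r": self.pooled_pearson_r,
            "pooled_rmse": self.pooled_rmse,
            "pearson_r_mean": self.pearson_r_mean,
            "pearson_r_sd": self.pearson_r_sd,
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
            "fold_metrics": self.fold_metrics.to_dict(orient="records"),
            "fold_assignment": self.fold_assignment.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


class DdgBoostModel:
    """Gradient-boosted trees for mutation-induced ΔΔG.

    Parameters
    ----------
    X, y
        Design matrix (one row per mutation record) and ΔΔG values
        (kcal/mol).
    complex_ids, pair_ids
        Per-row complex identifier (for complex-grouped folds) and
        mutation pair identifier (a mutation and its reverse always share
        a fold to avoid leakage).
    params
        Overrides for :data:`GBT_PARAMS`.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: np.ndarray,
        complex_ids: Optional[np.ndarray] = None,
        pair_ids: Optional[np.ndarray] = None,
        params: Optional[dict] = None,
    ):
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.X = X.reset_index(drop=True)
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        self.complex_ids = (
            np.asarray(complex_ids) if complex_ids is not None else np.arange(n).astype(str)
        )
        self.pair_ids = (
            np.asarray(pair_ids) if pair_ids is not None else np.arange(n).astype(str)
        )
        self.params = {**GBT_PARAMS, **(params or {})}

    @classmethod
    def from_feature_table(cls, table: FeatureTable, params: Optional[dict] = None) -> "DdgBoostModel":
        return cls(
            X=table.X, y=table.y,
            complex_ids=table.complex_ids, pair_ids=table.pair_ids,
            params=params,
        )

    def _make_regressor(self, seed: int):
        from xgboost import XGBRegressor

        p = self.params
        return XGBRegressor(
            max_depth=p["max_depth"],
            n_estimators=p["n_estimators"],
            learning_rate=p["learning_rate"],
            early_stopping_rounds=p["early_stopping_rounds"],
            n_jobs=1,
            random_state=seed,
            tree_method="hist",
            verbosity=0,
        )

    def _fit_one(self, X: np.ndarray, y: np.ndarray, seed: int):
        rng = np.random.default_rng(seed)
        n = len(y)
        n_val = max(1, int(round(self.params["validation_fraction"] * n)))
        perm = rng.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        reg = self._make_regressor(seed)
        reg.fit(X[fit_idx], y[fit_idx], eval_set=[(X[val_idx], y[val_idx])], verbose=False)
        return reg

    def fit(self, seed: int = 0) -> DdgResults:
        """Fit on all records (5% held out internally for early stopping)."""
        X = self.X.to_numpy()
        reg = self._fit_one(X, self.y, seed)
        pred = reg.predict(X)
        return DdgResults(
            model=reg,
            train_pearson_r=pearson_r(pred, self.y) if np.std(pred) > 0 else float("nan"),
            train_rmse=rmse(pred, self.y),
            n_train=len(self.y),
            best_iteration=getattr(reg, "best_iteration", None),
            feature_names=list(self.X.columns),
        )

    def _assign_folds(self, folds: int, seed: int, grouping: str) -> np.ndarray:
        keys = self.complex_ids if grouping == "complex" else self.pair_ids
        units = np.array(sorted(set(keys)))
        if len(units) < folds:
            raise ValueError(
                f"only {len(units)} {grouping} groups for {folds} folds — use fewer folds"
            )
        rng = np.random.default_rng(seed)
        rng.shuffle(units)
        fold_of_unit = {u: i % folds for i, u in enumerate(units)}
        return np.array([fold_of_unit[k] for k in keys])

    def crossvalidate(
        self,
        folds: int = 10,
        seed: int = 0,
        group_by_complex: bool = False,
    ) -> DdgCVResults:
        """k-fold CV with out-of-fold pooling of predictions.

        Records are grouped before splitting: by mutation pair by default
        (a mutation and its reverse never straddle folds), or by complex
        when ``group_by_complex`` is set, which prevents any information
        from a complex's other mutations reaching its test fold.
        """
        grouping = "complex" if group_by_complex else "mutation_pair"
        assignment = self._assign_folds(folds, seed, grouping)
        X = self.X.to_numpy()
        pooled_pred = np.empty_like(self.y)
        rows = []
        for f in range(folds):
            test = assignment == f
            reg = self._fit_one(X[~test], self.y[~test], seed + 1000 + f)
            pred = reg.predict(X[test])
            pooled_pred[test] = pred
            rp = (
                pearson_r(pred, self.y[test])
                if len(pred) >= 2 and np.std(pred) > 0 and np.std(self.y[test]) > 0
                else float("nan")
            )
            rows.append(
                {"fold": f, "n_test": int(test.sum()), "pearson_r": rp,
                 "rmse": rmse(pred, self.y[test])}
            )
        return DdgCVResults(
            fold_metrics=pd.DataFrame(rows),
            pooled_pearson_r=pearson_r(pooled_pred, self.y),
            pooled_rmse=rmse(pooled_pred, self.y),
            fold_assignment=assignment,
            predictions=pooled_pred,
            observed=self.y,
            seed=seed,
            folds=folds,
            grouping=grouping,
        )
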