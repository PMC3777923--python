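"""Two-stage experiment protocols and ranked-prediction evaluation.

Three protocols mirror the ablation design of the predictor:

- ``Pred_both`` — stage-1 survivors (non-zero filter + similarity threshold)
  re-ranked by the RVKDE likelihood score: the full two-stage predictor.
- ``Pred_1st`` — the same survivors ranked by profile similarity alone.
- ``Pred_2nd`` — the RVKDE alone, applied to random samples drawn from the
  non-zero-filter passers with the same positive/negative counts as the
  stage-1 survivors; repeated and averaged to remove sampling bias.

Evaluation works on ranked pair lists: precision among the top k, and the
area under the recall-precision curve up to a target recall, optionally
adjusted by the perfect predictor's AUC (which is exactly r at recall r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PPLinkError
from .features import encode_pairs
from .io import GeneRecord, PairSet
from .profiles import ProfileMatrix, StageOneResult, stage_one
from .rvkde import RVKDEModel, RVKDEParams, fit, grid_search_cv


@dataclass
class Bundle:
    """Everything one experiment needs: a query organism with profiles and
    labels, and a training organism supplying labeled pairs for the RVKDE."""

    query_records: list[GeneRecord]
    query_pairs: PairSet
    profile: ProfileMatrix  # column-normalized
    train_records: list[GeneRecord]
    train_pairs: PairSet
    manifest: dict = field(default_factory=dict)


@dataclass
class RankedPredictions:
    """Pairs ordered by descending score; ties broken by pair id.

    ``total_positives`` is the recall denominator: the number of related
    pairs in the full evaluation universe, not just in this ranking.
    """

    table: pd.DataFrame  # gene_a, gene_b, score, related
    total_positives: int

    @classmethod
    def from_arrays(cls, gene_a, gene_b, scores, related, total_positives):
        table = pd.DataFrame(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "score": np.asarray(scores, dtype=float),
                "related": np.asarray(related, dtype=bool),
            }
        )
        table = table.sort_values(
            ["score", "gene_a", "gene_b"], ascending=[False, True, True]
        ).reset_index(drop=True)
        if table.duplicated(["gene_a", "gene_b"]).any():
            raise PPLinkError("duplicate pairs in ranked predictions")
        return cls(table=table, total_positives=int(total_positives))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["related"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class EvalCurve:
    """Precision at every rank k, plus the recall denominator."""

    k: np.ndarray
    precision: np.ndarray
    total_positives: int

    def precision_at(self, k: int) -> float:
        if not 1 <= k <= len(self.k):
            raise PPLinkError(f"k={k} out of range 1..{len(self.k)}")
        return float(self.precision[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "precision": self.precision})


# --- training ----------------------------------------------------------------

def training_features(bundle: Bundle, normalize: bool = False):
    """686-dim features of the training organism's pairs, split by label."""
    X = encode_pairs(bundle.train_records, bundle.train_pairs.pairs, normalize=normalize)
    rel = np.array([p[2] for p in bundle.train_pairs.pairs], dtype=bool)
    return X[rel], X[~rel]

def train_model(bundle: Bundle, params: RVKDEParams) -> RVKDEModel:
    """Fit the RVKDE on the training organism's labeled pairs."""
    related, unrelated = training_features(bundle)
    return fit(related, unrelated, params)

def tune_model(
    bundle: Bundle, grid=None, folds: int = 5, seed: int = 0
) -> RVKDEParams:
    """Grid-search CV on the training organism, maximizing the F-measure."""
    related, unrelated = training_features(bundle)
    return grid_search_cv(related, unrelated, grid=grid, folds=folds, seed=seed)


# --- protocols ---------------------------------------------------------------

def _score_pairs(bundle: Bundle, model: RVKDEModel, pairs) -> np.ndarray:
    X = encode_pairs(bundle.query_records, pairs)
    return np.atleast_1d(model.score(X))


def run_pred_both(
    bundle: Bundle,
    model: RVKDEModel,
    nz: int = 1,
    sim_threshold: float = 0.0,
) -> RankedPredictions:
    """Full two-stage protocol: stage-1 survivors ranked by RVKDE score."""
    s1 = stage_one(bundle.profile, bundle.query_pairs, nz=nz, sim_threshold=sim_threshold)
    surv = s1.survivors()
    pairs = list(zip(surv["gene_a"], surv["gene_b"]))
    scores = (
        _score_pairs(bundle, model, pairs) if pairs else np.empty(0)
    )
    return RankedPredictions.from_arrays(
        surv["gene_a"].to_numpy(),
        surv["gene_b"].to_numpy(),
        scores,
        surv["related"].to_numpy(),
        total_positives=bundle.query_pairs.n_related,
    )


def run_pred_first(
    bundle: Bundle, nz: int = 1, sim_threshold: float = 0.0
) -> RankedPredictions:
    """Stage 1 alone: survivors ranked by profile similarity."""
    s1 = stage_one(bundle.profile, bundle.query_pairs, nz=nz, sim_threshold=sim_threshold)
    surv = s1.survivors()
    return RankedPredictions.from_arrays(
        surv["gene_a"].to_numpy(),
        surv["gene_b"].to_numpy(),
        surv["similarity"].to_numpy(),
        surv["related"].to_numpy(),
        total_positives=bundle.query_pairs.n_related,
    )


def run_pred_second(
    bundle: Bundle,
    model: RVKDEModel,
    nz: int = 1,
    sim_threshold: float = 0.0,
    repeats: int = 10,
    seed: int = 0,
    quota: tuple[int, int] | None = None,
) -> EvalCurve:
    """Stage 2 alone, with the stage-1 class quota.

    Draws ``repeats`` stratified random samples from the non-zero-filter
    passers, each with the same positive/negative counts as the stage-1
    survivors (or an explicit ``quota``), ranks each by RVKDE score and
    averages the precision@k curves pointwise.
    """
    s1 = stage_one(bundle.profile, bundle.query_pairs, nz=nz, sim_threshold=sim_threshold)
    nz_pass = s1.table[s1.table["passed_nz"]].reset_index(drop=True)
    if quota is None:
        surv = s1.survivors()
        quota = (int(surv["related"].sum()), int((~surv["related"]).sum()))
    n_pos, n_neg = quota
    pos = nz_pass[nz_pass["related"]]
    neg = nz_pass[~nz_pass["related"]]
    if n_pos > len(pos) or n_neg > len(neg):
        raise PPLinkError(
            f"quota ({n_pos} pos, {n_neg} neg) exceeds available "
            f"({len(pos)} pos, {len(neg)} neg) non-zero-filter passers"
        )
    if n_pos + n_neg == 0:
        return EvalCurve(
            k=np.empty(0, dtype=int),
            precision=np.empty(0),
            total_positives=bundle.query_pairs.n_related,
        )
    # RVKDE scores do not depend on the sample, so score every candidate once
    all_pairs = list(zip(nz_pass["gene_a"], nz_pass["gene_b"]))
    all_scores = _score_pairs(bundle, model, all_pairs)
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(repeats):
        pick = np.concatenate(
            [
                rng.choice(pos.index.to_numpy(), size=n_pos, replace=False),
                rng.choice(neg.index.to_numpy(), size=n_neg, replace=False),
            ]
        ).astype(int)
        sample = nz_pass.loc[pick]
        ranked = RankedPredictions.from_arrays(
            sample["gene_a"].to_numpy(),
            sample["gene_b"].to_numpy(),
            all_scores[pick],
            sample["related"].to_numpy(),
            total_positives=bundle.query_pairs.n_related,
        )
        curves.append(curve_from_ranked(ranked))
    return average_curves(curves)


# --- metrics -----------------------------------------------------------------

def curve_from_ranked(ranked: RankedPredictions) -> EvalCurve:
    labels = ranked.labels.astype(float)
    k = np.arange(1, len(labels) + 1)
    return EvalCurve(
        k=k,
        precision=np.cumsum(labels) / k,
        total_positives=ranked.total_positives,
    )


def average_curves(curves: list[EvalCurve]) -> EvalCurve:
    if not curves:
        raise PPLinkError("no curves to average")
    lengths = {len(c.k) for c in curves}
    if len(lengths) != 1:
        raise PPLinkError(f"cannot average curves of different lengths: {lengths}")
    return EvalCurve(
        k=curves[0].k.copy(),
        precision=np.mean([c.precision for c in curves], axis=0),
        total_positives=curves[0].total_positives,
    )


def precision_at_k(ranked: RankedPredictions, k: int) -> float:
    """Fraction of true related pairs among the top k predictions."""
    if not 1 <= k <= len(ranked):
        raise PPLinkError(f"k={k} out of range 1..{len(ranked)}")
    return float(ranked.labels[:k].mean())


def auc_at_recall(
    ranked: RankedPredictions, r: float, total_positives: int | None = None
) -> float:
    """Area under the recall(x)-precision(y) curve from recall 0 to r.

    The curve is sampled at every rank where a positive is retrieved,
    anchored at recall 0 with the first sampled precision, integrated by
    trapezoids and linearly interpolated to end exactly at ``r``. Recall
    beyond the ranking's reach contributes nothing. A perfect ranking gives
    exactly r.
    """
    if not 0 < r <= 1:
        raise PPLinkError(f"target recall must be in (0, 1], got {r}")
    P = ranked.total_positives if total_positives is None else total_positives
    if P < 1:
        raise PPLinkError("no positives: recall is undefined")
    labels = ranked.labels
    tp = np.cumsum(labels)
    pos_ranks = np.flatnonzero(labels) + 1
    if pos_ranks.size == 0:
        return 0.0
    rec_pts = tp[pos_ranks - 1] / P
    prec_pts = tp[pos_ranks - 1] / pos_ranks
    rec = np.concatenate([[0.0], rec_pts])
    prec = np.concatenate([[prec_pts[0]], prec_pts])
    target = min(r, float(rec[-1]))
    if target <= 0:
        return 0.0
    keep = rec < target
    rr = np.append(rec[keep], target)
    pp = np.append(prec[keep], np.interp(target, rec, prec))
    return float(np.trapezoid(pp, rr))


def adjusted_auc(auc: float, r: float) -> float:
    """AUC divided by the perfect predictor's AUC at the same recall (= r)."""
    if r <= 0:
        raise PPLinkError(f"target recall must be positive, got {r}")
    return auc / r
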