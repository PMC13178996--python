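"""The suite-conformer classifier: model and results objects.

Given trained clusters of suites — each carrying low-detail (MUCCSS)
members and a multiset of conformer-class labels — the classifier
summarises every cluster by its Fréchet mean and tangent covariance and
predicts the cluster of a new low-detail suite in two gated stages:

1. the pucker configuration pair (P33/P32/P23/P22) is read off the
   Pperp criterion, restricting the candidate clusters,
2. within the pair, a Gaussian posterior with cluster sizes as prior
   weights ranks the clusters,

       log p~(C_i | W) = log|C_i| - 1/2 log det RS_i
                         - 1/2 T(W)^T RS_i^{-1} T(W),

   where T(W) are tangent coordinates at the cluster's Fréchet mean and
   RS_i = lambda S_i + (1 - lambda) S_1 is the cluster covariance
   regularised towards the covariance S_1 of the dominant (largest P33,
   A-form) cluster so that small clusters, whose spread cannot fill all
   7 dimensions, still yield invertible matrices.  The Mahalanobis term
   is the only part depending on the test suite; posteriors are
   normalised within the pair.  Because of the regularisation, the
   posteriors carry "regularised" credibility (see the results object's
   metadata).

The model/results pair follows the usual statistical-modelling layout:
build a :class:`RNAPrecis` model from clustered data (or straight from
suites via :meth:`RNAPrecis.from_suites`), call ``fit()`` and use the
returned :class:`RNAPrecisResults` for prediction, evaluation,
summaries and plots.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from . import muccss
from .clustering import (AgeParams, ClusterModel, DEFAULT_AGE_PARAMS,
                         ModeHuntConfig, mint_age)
from .muccss import ChartError, FrechetSummary, LandmarkSet, MuccssPoint
from .structure_io import LabelTable, SuiteAtoms
from .suite_geometry import GeometryError, pucker_pair, suite_dihedrals

log = logging.getLogger(__name__)

__all__ = [
    "ClusterSummary",
    "PredictionResult",
    "EvaluationRecord",
    "RNAPrecis",
    "RNAPrecisResults",
    "log_unnormalized_posterior",
    "evaluate_predictions",
]

PAIRS = ("P33", "P32", "P23", "P22")


@dataclass
class ClusterSummary:
    """Fitted per-cluster quantities used by the posterior."""

    cluster_id: Tuple[str, int]
    size: int
    labels: Counter
    mean: MuccssPoint
    covariance: np.ndarray
    reg_covariance: np.ndarray = None
    _cho: tuple = field(default=None, repr=False)
    _logdet: float = field(default=None, repr=False)

    def finalize(self):
        """Factor the regularised covariance; fails on non-PD input."""
        try:
            c, low = cho_factor(self.reg_covariance, lower=True)
        except np.linalg.LinAlgError as exc:
            evals = np.linalg.eigvalsh(self.reg_covariance)
            raise np.linalg.LinAlgError(
                f"regularised covariance of cluster {self.cluster_id} is "
                f"not positive definite (smallest eigenvalue "
                f"{evals[0]:.3e})") from exc
        self._cho = (c, low)
        self._logdet = float(2.0 * np.sum(np.log(np.diag(c))))

    def mahalanobis_sq(self, w: MuccssPoint) -> float:
        t = muccss.tangent_coords(w, self.mean)
        return float(t @ cho_solve(self._cho, t))

    @property
    def logdet(self) -> float:
        return self._logdet


def log_unnormalized_posterior(w: MuccssPoint, summary: ClusterSummary
                               ) -> float:
    """log|C_i| - 1/2 log det RS_i - 1/2 Mahalanobis^2(W; cluster)."""
    return (np.log(summary.size) - 0.5 * summary.logdet
            - 0.5 * summary.mahalanobis_sq(w))


@dataclass
class PredictionResult:
    """Per-suite prediction: pucker gate, ranked posteriors, winner."""

    suite_id: tuple
    pucker_pair: Optional[str]
    cluster_ids: List[Tuple[str, int]]
    posteriors: np.ndarray
    mahalanobis: Dict[Tuple[str, int], float]
    best: Optional[Tuple[str, int]]
    predicted_conformers: frozenset
    note: str = ""

    @property
    def ok(self) -> bool:
        return self.best is not None


@dataclass
class EvaluationRecord:
    suite_id: tuple
    category: str  # prediction_match / prediction_mismatch / pucker_mismatch
    answers: frozenset
    predicted: Optional[Tuple[str, int]]
    predicted_conformers: frozenset
    flags: str = ""


class RNAPrecis:
    """Suite-conformer classification model.

    Parameters
    ----------
    clusters
        Trained clusters with low-detail members: either a flat list of
        :class:`~rnaprecis.clustering.ClusterModel` whose ``ld_points``
        hold MuccssPoint members, or a mapping pucker pair -> such list.
    lam
        Covariance regularisation weight, 0.5 by default.  Interior
        values (0, 1) are the intended regime; the endpoints are
        admitted for their exact identities (lam = 1: RS_i = S_i, no
        regularisation; lam = 0: RS_i = S_1 for every cluster).
    """

    def __init__(self, clusters, lam: float = 0.5):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.lam = float(lam)
        if isinstance(clusters, Mapping):
            flat = [c for pair in clusters for c in clusters[pair]]
        else:
            flat = list(clusters)
        if not flat:
            raise ValueError("no clusters to train on")
        self.clusters: List[ClusterModel] = flat

    # -- construction from raw suites ------------------------------------

    @classmethod
    def from_suites(cls, suites: Sequence[SuiteAtoms], labels: LabelTable,
                    age_params: Optional[Mapping[str, AgeParams]] = None,
                    mode_hunt: ModeHuntConfig = ModeHuntConfig(),
                    lam: float = 0.5,
                    gate_mode: str = "HD") -> "RNAPrecis":
        """Run the full training side on labelled high-detail suites.

        Suites are gated into pucker-pair sets (high-detail ribose
        geometry by default), suites whose low-detail Pperp gate
        disagrees with the high-detail call are dropped (pucker-ambiguous
        training data), each pair set is clustered on the 7-torus, and
        the clusters' low-detail representations are attached.
        """
        age_params = dict(DEFAULT_AGE_PARAMS, **(age_params or {}))
        lookup = labels.lookup()
        per_pair: Dict[str, list] = {p: [] for p in PAIRS}
        for s in suites:
            try:
                hd_pair = pucker_pair(s, gate_mode)
                angles = suite_dihedrals(s)
                w = muccss.to_muccss(LandmarkSet.from_suite(s))
            except GeometryError as exc:
                log.info("suite %s skipped in training: %s", s.suite_id, exc)
                continue
            if s.next_P is not None and pucker_pair(s, "LD") != hd_pair:
                log.info("suite %s skipped: pucker-ambiguous "
                         "(Pperp gate disagrees)", s.suite_id)
                continue
            per_pair[hd_pair].append(
                (s.suite_id, angles, w, lookup.get(s.suite_id)))
        clusters: List[ClusterModel] = []
        rng = np.random.default_rng(mode_hunt.seed)
        for pair in PAIRS:
            rows = per_pair[pair]
            if not rows:
                continue
            ids = [r[0] for r in rows]
            pts = np.array([r[1] for r in rows])
            ws = [r[2] for r in rows]
            labs = [r[3] if r[3] is not None else "??" for r in rows]
            pair_clusters, outliers = mint_age(
                pts, age_params[pair], pucker_pair=pair, suite_ids=ids,
                labels=labs, mode_hunt=mode_hunt, rng=rng)
            index = {sid: w for sid, w in zip(ids, ws)}
            for c in pair_clusters:
                c.ld_points = [index[sid] for sid in c.members]
            clusters.extend(pair_clusters)
            if len(outliers):
                log.info("%s: %d training outliers left unclustered",
                         pair, len(outliers))
        return cls(clusters, lam=lam)

    # -- estimation -------------------------------------------------------

    def fit(self) -> "RNAPrecisResults":
        """Estimate per-cluster Fréchet means and tangent covariances,
        regularise towards the largest-P33-cluster covariance, and
        return the results object."""
        summaries: Dict[str, List[ClusterSummary]] = {p: [] for p in PAIRS}
        for c in self.clusters:
            if not c.ld_points:
                raise ValueError(
                    f"cluster {c.cluster_id} carries no low-detail members")
            fs: FrechetSummary = muccss.frechet_summary(c.ld_points)
            if fs.n < 2:
                log.warning("cluster %s has n=%d: zero covariance, pure "
                            "regulariser", c.cluster_id, fs.n)
            pair = c.cluster_id[0]
            summaries[pair].append(ClusterSummary(
                cluster_id=c.cluster_id, size=fs.n,
                labels=Counter(c.conformer_labels),
                mean=fs.mean, covariance=fs.covariance))
        # reference covariance: the single largest P33 cluster (the
        # A-form-dominated one); pooled fallback if P33 is absent
        if summaries["P33"]:
            ref = max(summaries["P33"], key=lambda s: s.size)
            s1 = ref.covariance
        else:
            log.warning("no P33 clusters: falling back to the pooled "
                        "covariance as regulariser")
            allc = [s for p in PAIRS for s in summaries[p]]
            s1 = sum(s.covariance * (s.size - 1) for s in allc) / max(
                sum(s.size - 1 for s in allc), 1)
        for p in PAIRS:
            for s in summaries[p]:
                s.reg_covariance = (self.lam * s.covariance
                                    + (1.0 - self.lam) * s1)
                s.finalize()
        return RNAPrecisResults(model=self, summaries=summaries,
                                reference_covariance=s1)


class RNAPrecisResults:
    """Fitted classifier: cluster summaries, prediction and evaluation.

    Posterior values reported by :meth:`predict` are valid posterior
    probabilities of a model with *regularised* covariances; their
    credibility regions inherit that regularisation.
    """

    def __init__(self, model: RNAPrecis,
                 summaries: Dict[str, List[ClusterSummary]],
                 reference_covariance: np.ndarray):
        self.model = model
        self.summaries = summaries
        self.reference_covariance = reference_covariance

    @property
    def lam(self) -> float:
        return self.model.lam

    def pair_summaries(self, pair: str) -> List[ClusterSummary]:
        return self.summaries.get(pair, [])

    # -- prediction -------------------------------------------------------

    def predict_point(self, w: MuccssPoint, pair: str,
                      suite_id: tuple = ()) -> PredictionResult:
        """Rank the clusters of one pucker-pair set for a MUCCSS point."""
        cands = self.pair_summaries(pair)
        logps, ids, mahal = [], [], {}
        for s in cands:
            try:
                m2 = s.mahalanobis_sq(w)
            except ChartError:
                log.info("suite %s: cluster %s excluded (outside its "
                         "hemisphere chart)", suite_id, s.cluster_id)
                continue
            mahal[s.cluster_id] = m2
            logps.append(np.log(s.size) - 0.5 * s.logdet - 0.5 * m2)
            ids.append(s.cluster_id)
        if not logps:
            return PredictionResult(
                suite_id=suite_id, pucker_pair=pair, cluster_ids=[],
                posteriors=np.array([]), mahalanobis={}, best=None,
                predicted_conformers=frozenset(),
                note="no cluster admits this suite in its chart")
        logps = np.asarray(logps)
        post = np.exp(logps - logps.max())
        post /= post.sum()
        # rank by posterior, deterministic tie-break on cluster index
        order = sorted(range(len(ids)), key=lambda i: (-post[i], ids[i][1]))
        ids = [ids[i] for i in order]
        post = post[order]
        best = ids[0]
        labels = next(s for s in cands if s.cluster_id == best).labels
        return PredictionResult(
            suite_id=suite_id, pucker_pair=pair, cluster_ids=ids,
            posteriors=post, mahalanobis=mahal, best=best,
            predicted_conformers=frozenset(labels))

    def predict(self, suites: Iterable[SuiteAtoms]) -> List[PredictionResult]:
        """Gate each suite by the Pperp criterion and rank the clusters
        of its pucker-pair set; suites without a next-residue P (or with
        degenerate geometry) yield a no-prediction result."""
        out = []
        for s in suites:
            try:
                pair = pucker_pair(s, "LD")
                w = muccss.to_muccss(LandmarkSet.from_suite(s))
            except (GeometryError, KeyError) as exc:
                out.append(PredictionResult(
                    suite_id=s.suite_id, pucker_pair=None, cluster_ids=[],
                    posteriors=np.array([]), mahalanobis={}, best=None,
                    predicted_conformers=frozenset(), note=str(exc)))
                continue
            out.append(self.predict_point(w, pair, suite_id=s.suite_id))
        return out

    # -- evaluation -------------------------------------------------------

    def conformer_pairs(self) -> Dict[str, set]:
        """conformer class -> set of pucker pairs of clusters containing it."""
        mapping: Dict[str, set] = {}
        for p in PAIRS:
            for s in self.summaries[p]:
                for lab in s.labels:
                    mapping.setdefault(lab, set()).add(p)
        return mapping

    def evaluate(self, predictions: Sequence[PredictionResult],
                 answers: LabelTable
                 ) -> Tuple[List[EvaluationRecord], pd.DataFrame]:
        return evaluate_predictions(predictions, answers,
                                    self.conformer_pairs())

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted cluster models."""
        lines = [
            "Suite conformer classifier (regularised Gaussian posterior)",
            f"lambda = {self.lam:.3f}   "
            f"clusters = {sum(len(v) for v in self.summaries.values())}",
            "-" * 72,
            f"{'pair':<6}{'cluster':<9}{'n':>5}  {'log det RS':>11}  "
            f"conformers",
            "-" * 72,
        ]
        for p in PAIRS:
            for s in self.summaries[p]:
                labs = ", ".join(f"{k}:{v}" for k, v in
                                 sorted(s.labels.items(),
                                        key=lambda kv: (-kv[1], kv[0])))
                lines.append(f"{p:<6}{s.cluster_id[1]:<9}{s.size:>5}  "
                             f"{s.logdet:>11.2f}  {labs}")
        lines.append("-" * 72)
        lines.append("posteriors are normalised within each pucker-pair set;")
        lines.append("credibility is that of the regularised-covariance model")
        return "\n".join(lines)

    def plot_clusters(self, pair: str = "P33", ax=None):
        """Scatter of cluster means in the (phi1, phi2) glycosidic
        longitude plane with per-cluster sizes; returns the axes."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.pair_summaries(pair):
            pol = s.mean.polar()
            ax.scatter(pol["phi1"], pol["phi2"], s=20 + 2 * s.size)
            ax.annotate(str(s.cluster_id[1]), (pol["phi1"], pol["phi2"]))
        ax.set_xlabel(r"$\phi_1$ (deg)")
        ax.set_ylabel(r"$\phi_2$ (deg)")
        ax.set_title(f"{pair} cluster means")
        return ax

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        blob = {"lambda": self.lam,
                "reference_covariance":
                    np.asarray(self.reference_covariance).ravel().tolist(),
                "clusters": []}
        for p in PAIRS:
            for s in self.summaries[p]:
                m = s.mean
                blob["clusters"].append({
                    "pair": p, "index": s.cluster_id[1], "n": s.size,
                    "labels": dict(s.labels),
                    "mean": {"d2": m.d2, "d3": m.d3, "alpha": m.alpha,
                             "s1": m.s1.tolist(), "s2": m.s2.tolist()},
                    "covariance": s.covariance.ravel().tolist(),
                })
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def load(cls, path) -> "RNAPrecisResults":
        blob = json.loads(Path(path).read_text())
        clusters = []
        for c in blob["clusters"]:
            m = c["mean"]
            cm = ClusterModel(
                cluster_id=(c["pair"], c["index"]),
                members=list(range(c["n"])), hd_points=np.empty((0, 7)),
                conformer_labels=Counter(c["labels"]))
            cm.ld_summary = FrechetSummary(
                mean=MuccssPoint(d2=m["d2"], d3=m["d3"], alpha=m["alpha"],
                                 s1=np.array(m["s1"]), s2=np.array(m["s2"])),
                covariance=np.array(c["covariance"]).reshape(7, 7),
                n=c["n"], frechet_value=float("nan"))
            clusters.append(cm)
        model = RNAPrecis.__new__(RNAPrecis)
        model.lam = float(blob["lambda"])
        model.clusters = clusters
        summaries: Dict[str, List[ClusterSummary]] = {p: [] for p in PAIRS}
        for cm in clusters:
            fs = cm.ld_summary
            summaries[cm.cluster_id[0]].append(ClusterSummary(
                cluster_id=cm.cluster_id, size=fs.n,
                labels=Counter(cm.conformer_labels),
                mean=fs.mean, covariance=fs.covariance))
        s1 = np.array(blob["reference_covariance"]).reshape(7, 7)
        for p in PAIRS:
            for s in summaries[p]:
                s.reg_covariance = (model.lam * s.covariance
                                    + (1.0 - model.lam) * s1)
                s.finalize()
        return cls(model=model, summaries=summaries, reference_covariance=s1)


def evaluate_predictions(predictions: Sequence[PredictionResult],
                         answers: LabelTable,
                         conformer_pairs: Mapping[str, set]
                         ) -> Tuple[List[EvaluationRecord], pd.DataFrame]:
    """Three-way evaluation against probable-answer conformers.

    For each prediction the probable answers (one or more conformer
    classes) are read from the manifest.  The categories are:

    prediction_match
        the predicted cluster's label multiset contains at least one
        answer conformer (clusters holding several conformers match any
        of them);
    pucker_mismatch
        no answer conformer belongs to the gated pucker-pair set — the
        Pperp gate and the probable answer disagree about the puckers;
    prediction_mismatch
        same pucker-pair set, but the predicted cluster contains no
        answer conformer.  Answers never clustered during training are
        flagged ``unclustered-answer`` (they can only mismatch).

    Returns the per-suite records and a per-pair summary table with
    counts and percentages.
    """
    df = answers.df
    if "answer_conformer" not in df.columns:
        raise ValueError("manifest lacks an answer_conformer column")
    ans_map: Dict[tuple, set] = {}
    ans_pair: Dict[tuple, set] = {}
    for r in df.itertuples():
        sid = (r.structure_id, r.chain, int(r.resnum), r.icode)
        for a in str(r.answer_conformer).split(";"):
            a = a.strip()
            if a:
                ans_map.setdefault(sid, set()).add(a)
                pr = conformer_pairs.get(a, set())
                explicit = getattr(r, "answer_pucker_pair", "")
                if explicit:
                    pr = pr | {explicit}
                ans_pair.setdefault(sid, set()).update(pr)

    records: List[EvaluationRecord] = []
    for pred in predictions:
        sid = pred.suite_id
        if sid not in ans_map:
            raise KeyError(f"no probable answer for suite {sid}")
        answers_here = frozenset(ans_map[sid])
        flags = []
        if pred.best is None:
            cat = "prediction_mismatch"
            flags.append("no-prediction")
        elif pred.pucker_pair not in ans_pair[sid]:
            cat = "pucker_mismatch"
        elif answers_here & pred.predicted_conformers:
            cat = "prediction_match"
        else:
            cat = "prediction_mismatch"
            if not any(a in conformer_pairs for a in answers_here):
                flags.append("unclustered-answer")
        records.append(EvaluationRecord(
            suite_id=sid, category=cat, answers=answers_here,
            predicted=pred.best,
            predicted_conformers=pred.predicted_conformers,
            flags=";".join(flags)))

    rows = []
    by_pair: Dict[str, List[EvaluationRecord]] = {}
    for pred, rec in zip(predictions, records):
        by_pair.setdefault(pred.pucker_pair or "??", []).append(rec)
    for pair in list(PAIRS) + sorted(set(by_pair) - set(PAIRS)):
        recs = by_pair.get(pair)
        if not recs:
            continue
        n = len(recs)
        cnt = Counter(r.category for r in recs)
        row = {"dataset": pair, "count": n}
        for cat, col in (("prediction_match", "matches"),
                         ("prediction_mismatch", "mismatches"),
                         ("pucker_mismatch", "pucker_mismatches")):
            row[col] = cnt.get(cat, 0)
            row[col + "_pct"] = round(100.0 * cnt.get(cat, 0) / n, 1)
        rows.append(row)
    total = {"dataset": "all", "count": len(records)}
    cnt = Counter(r.category for r in records)
    for cat, col in (("prediction_match", "matches"),
                     ("prediction_mismatch", "mismatches"),
                     ("pucker_mismatch", "pucker_mismatches")):
        total[col] = cnt.get(cat, 0)
        total[col + "_pct"] = round(
            100.0 * cnt.get(cat, 0) / max(len(records), 1), 1)
    rows.append(total)
    return records, pd.DataFrame(rows)
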