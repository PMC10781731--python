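"""Subsample-based cluster stability.

"How often do samples end up in the same cluster if we train the model
again?"  The full pipeline (autoencoder pretraining + KL self-training) is
retrained on R random subsets, each holding a fraction (default 90%) of the
samples.  A *complete model*, trained once on all samples, anchors the
cluster labels: each subset run's clusters are mapped onto the complete
model's clusters by iterative exclusive Jaccard matching (highest Jaccard
mapped first, no two subset clusters sharing a target).  Each sample's
*reference label* is the mapped label it received most often.  Cluster-wise
stability is the Jaccard coefficient per (reference cluster, subset);
sample-wise stability is the fraction of subsets containing the sample that
placed it in its reference cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MixedDataset


@dataclass
class SubsetPlan:
    """Reproducible plan of R subsets of ceil(fraction * n) sample indices."""

    n: int
    fraction: float = 0.9
    R: int = 1000
    seed: int = 0
    subsets: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not self.subsets:
            rng = np.random.default_rng(self.seed)
            size = int(np.ceil(self.fraction * self.n))
            self.subsets = [np.sort(rng.choice(self.n, size=size, replace=False))
                            for _ in range(self.R)]

    def run_seed(self, r: int) -> int:
        """Seed for subset run r (0-based); the complete model uses the plan
        seed itself, runs use plan seed + 1 + r, kept below 2^31."""
        return (self.seed + 1 + r) % (2 ** 31)


def make_subsets(n: int, fraction: float = 0.9, R: int = 1000, seed: int = 0) -> SubsetPlan:
    return SubsetPlan(n=n, fraction=fraction, R=R, seed=seed)


def jaccard(a, b) -> float:
    """|A ∩ B| / |A ∪ B| between two sample-id sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def greedy_exclusive_map(subset_labels: np.ndarray, complete_labels: np.ndarray,
                         subset_indices: np.ndarray) -> dict[int, int]:
    """Map subset clusters to complete-model clusters, best Jaccard first.

    ``complete_labels`` is the complete model's label vector over all
    samples; comparisons are restricted to the samples in the subset.  The
    pair with the globally highest Jaccard is mapped first and both clusters
    leave contention, so the mapping is injective.  Ties break to the lowest
    subset-cluster index, then lowest complete-cluster index.  Subset
    clusters left over when complete clusters run out stay unmapped.
    """
    subset_indices = np.asarray(subset_indices)
    complete_on_subset = np.asarray(complete_labels)[subset_indices]
    subset_labels = np.asarray(subset_labels)
    sub_clusters = np.unique(subset_labels)
    comp_clusters = np.unique(complete_on_subset)
    pairs = []
    for a in sub_clusters:
        set_a = set(subset_indices[subset_labels == a])
        for b in comp_clusters:
            set_b = set(subset_indices[complete_on_subset == b])
            pairs.append((jaccard(set_a, set_b), int(a), int(b)))
    # highest Jaccard first; ties by lowest subset label then complete label
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, int] = {}
    used_targets: set[int] = set()
    for j, a, b in pairs:
        if a in mapping or b in used_targets:
            continue
        mapping[a] = b
        used_targets.add(b)
    return mapping


def derive_reference_labels(mapped_labels: pd.DataFrame,
                            fallback: pd.Series | None = None) -> pd.Series:
    """Modal mapped label per sample over all subsets containing it.

    *mapped_labels* is samples x subsets with NaN where a sample was not in
    the subset (or its cluster went unmapped).  Ties break to the lowest
    label index.  A sample covered by no subset (possible for small R) takes
    its *fallback* label (the complete model's) if given, else this is an
    error.
    """
    uncovered = mapped_labels.index[mapped_labels.notna().sum(axis=1) == 0]
    if len(uncovered) and fallback is None:
        raise ValueError(f"samples never covered by any subset: {list(uncovered)[:5]}")

    def modal(row):
        counts = row.dropna().astype(int).value_counts()
        top = counts[counts == counts.max()].index
        return int(min(top))

    covered = mapped_labels.index.difference(uncovered)
    out = pd.Series(0, index=mapped_labels.index, dtype=int)
    out.loc[covered] = mapped_labels.loc[covered].apply(modal, axis=1)
    if len(uncovered):
        out.loc[uncovered] = fallback.loc[uncovered].astype(int)
    return out


def clusterwise_stability(mapped_labels: pd.DataFrame, reference_labels: pd.Series,
                          plan: SubsetPlan) -> pd.DataFrame:
    """Per-(subset, reference cluster) Jaccard between the samples mapped to
    the cluster and the samples whose reference label is the cluster, both
    restricted to the subset.  A cluster with no mapped samples in a run is
    recorded as missing and excluded from means."""
    clusters = sorted(reference_labels.unique())
    ids = mapped_labels.index
    rows = []
    for r in range(plan.R):
        in_subset = ids[plan.subsets[r]]
        col = mapped_labels.iloc[:, r].loc[in_subset]
        ref = reference_labels.loc[in_subset]
        for c in clusters:
            mapped_set = set(col.index[col == c])
            ref_set = set(ref.index[ref == c])
            if not mapped_set:
                val = np.nan
            elif not ref_set:
                val = 0.0
            else:
                val = jaccard(mapped_set, ref_set)
            rows.append((r, c, val))
    return pd.DataFrame(rows, columns=["subset", "reference_cluster", "jaccard"])


def samplewise_stability(mapped_labels: pd.DataFrame, reference_labels: pd.Series,
                         plan: SubsetPlan) -> pd.Series:
    """Per sample: fraction of subsets containing it that placed it in its
    reference cluster."""
    match = mapped_labels.eq(reference_labels, axis=0)
    present = mapped_labels.notna()
    return match.sum(axis=1) / present.sum(axis=1)


class StabilityReport:
    """Assembled stability results for one clustering pipeline."""

    def __init__(self, clusterwise: pd.DataFrame, samplewise: pd.Series,
                 reference_labels: pd.Series, converged: list[bool],
                 plan: SubsetPlan):
        self.clusterwise = clusterwise
        self.samplewise = samplewise
        self.reference_labels = reference_labels
        self.converged = converged
        self.plan = plan

    @property
    def overall_jaccard(self) -> float:
        """Mean of the cluster-wise Jaccard coefficients over all
        (reference cluster, subset) cells."""
        return float(self.clusterwise["jaccard"].mean(skipna=True))

    def per_cluster_summary(self) -> pd.DataFrame:
        g = self.clusterwise.groupby("reference_cluster")["jaccard"]
        return pd.DataFrame({"median": g.median(), "q1": g.quantile(0.25),
                             "q3": g.quantile(0.75), "mean": g.mean(),
                             "n_missing": g.apply(lambda s: int(s.isna().sum()))})

    def summary(self) -> str:
        lines = ["Cluster stability report", "=" * 40,
                 f"subsets:              {self.plan.R} x {self.plan.fraction:.0%}",
                 f"overall Jaccard:      {self.overall_jaccard:.3f}",
                 f"median sample-wise:   {float(self.samplewise.median()):.3f}",
                 f"mean sample-wise:     {float(self.samplewise.mean()):.3f}",
                 f"non-converged runs:   {sum(not c for c in self.converged)}"]
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        """CSV pair + JSON summary (lossless for reload)."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clusterwise.to_csv(outdir / "clusterwise_jaccard.csv", index=False)
        per_sample = pd.DataFrame({"stability": self.samplewise,
                                   "reference_label": self.reference_labels})
        per_sample.to_csv(outdir / "samplewise_stability.csv", index_label="sample_id")
        summary = {
            "overall_jaccard": self.overall_jaccard,
            "median_samplewise": float(self.samplewise.median()),
            "mean_samplewise": float(self.samplewise.mean()),
            "per_cluster_median": {str(k): float(v) for k, v in
                                   self.per_cluster_summary()["median"].items()},
            "R": self.plan.R, "fraction": self.plan.fraction,
            "seed": self.plan.seed, "n": self.plan.n,
            "converged": self.converged,
        }
        (outdir / "stability_summary.json").write_text(json.dumps(summary, indent=2))

    @staticmethod
    def read(outdir) -> "StabilityReport":
        from pathlib import Path
        outdir = Path(outdir)
        summary = json.loads((outdir / "stability_summary.json").read_text())
        clusterwise = pd.read_csv(outdir / "clusterwise_jaccard.csv")
        per_sample = pd.read_csv(outdir / "samplewise_stability.csv",
                                 index_col="sample_id")
        per_sample.index = per_sample.index.astype(str)
        plan = SubsetPlan(n=summary["n"], fraction=summary["fraction"],
                          R=summary["R"], seed=summary["seed"])
        return StabilityReport(clusterwise, per_sample["stability"],
                               per_sample["reference_label"],
                               summary["converged"], plan)


def run_stability(pipeline_factory, ds: MixedDataset, plan: SubsetPlan,
                  run_seeds: list[int] | None = None,
                  complete=None) -> StabilityReport:
    """Full stability procedure.

    *pipeline_factory(ds, seed)* must train a fresh full pipeline
    (pretraining + clustering) and return an object with ``labels_`` and
    ``converged_``.  The complete model is trained on all samples with the
    plan seed (or passed in precomputed via *complete*); each subset run
    gets a seed derived from the plan seed.
    """
    if plan.n != ds.n_samples:
        raise ValueError("plan was made for a different number of samples")
    run_seeds = run_seeds or [plan.run_seed(r) for r in range(plan.R)]
    if complete is None:
        complete = pipeline_factory(ds, plan.seed)
    complete_labels = np.asarray(complete.labels_)
    ids = ds.sample_ids
    mapped = pd.DataFrame(np.nan, index=ids,
                          columns=[f"run{r}" for r in range(plan.R)])
    converged = []
    for r in range(plan.R):
        sub_idx = plan.subsets[r]
        result = pipeline_factory(ds.take(sub_idx), run_seeds[r])
        converged.append(bool(getattr(result, "converged_", True)))
        mapping = greedy_exclusive_map(np.asarray(result.labels_),
                                       complete_labels, sub_idx)
        mapped_run = np.array([mapping.get(int(l), -1) for l in result.labels_],
                              float)
        mapped_run[mapped_run < 0] = np.nan  # unmapped leftover clusters
        mapped.iloc[sub_idx, r] = mapped_run
    reference = derive_reference_labels(
        mapped, fallback=pd.Series(complete_labels, index=ids))
    return StabilityReport(
        clusterwise_stability(mapped, reference, plan),
        samplewise_stability(mapped, reference, plan),
        reference, converged, plan)
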