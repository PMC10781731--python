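"""Cross-cohort cluster generalisability.

A frozen clustering model trained on a development cohort is applied, with
no retraining, to an external cohort scaled with the development cohort's
statistics.  Each external cluster is then mapped — non-exclusively — to
its most similar development cluster in three spaces:

* input space: per-cluster profiles (means of standardised numeric
  variables, proportions of binary variables), compared by Gower distance;
* outcome space: [min-max-scaled mean LOS, mortality rate, diagnosis-
  category proportions], compared by Euclidean distance (vasoactive
  requirement excluded by default because of systematic cohort shift);
* latent space: per-cluster mean latent features, compared by Euclidean
  distance.

A well-generalising model maps external cluster j to development cluster j
("identity") — expected to hold exactly in latent space, since that is the
space the clusters are defined in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MixedDataset, OutcomeTable


@dataclass
class ClusterProfile:
    """Per-cluster representation in one comparison space."""

    space: str                      # input | outcome | latent
    vectors: pd.DataFrame           # rows: cluster labels; columns: components
    numeric_cols: list[str] = field(default_factory=list)  # Gower range-normalised
    binary_cols: list[str] = field(default_factory=list)   # Gower |proportion diff|

    @property
    def clusters(self) -> list[int]:
        return list(self.vectors.index)


def profile_input(ds: MixedDataset, labels: np.ndarray) -> ClusterProfile:
    """Within-cluster means of (standardised) numeric variables and
    within-cluster proportions of ones for binary variables."""
    labels = np.asarray(labels)
    if len(labels) != ds.n_samples:
        raise ValueError("labels must cover all samples")
    rows = {}
    for c in np.unique(labels):
        mask = labels == c
        rows[int(c)] = pd.concat([ds.numeric.iloc[mask].mean(axis=0),
                                  ds.binary.iloc[mask].mean(axis=0)])
    vectors = pd.DataFrame(rows).T.sort_index()
    return ClusterProfile("input", vectors,
                          numeric_cols=list(ds.numeric.columns),
                          binary_cols=list(ds.binary.columns))


def profile_outcome(outcomes: OutcomeTable, labels: np.ndarray,
                    diagnosis_vocabulary: list[str],
                    include_vasoactive: bool = False) -> ClusterProfile:
    """[min-max-scaled mean LOS, mortality rate, diagnosis proportions].

    LOS is min-max scaled across the cluster means within this cohort, so
    the LOS component spans [0, 1] per cohort.  The diagnosis vocabulary
    must be shared across cohorts (union; absent categories count 0).
    """
    labels = np.asarray(labels)
    frame = outcomes.frame
    if len(labels) != len(frame):
        raise ValueError("labels must cover all outcome rows")
    clusters = sorted(int(c) for c in np.unique(labels))
    mean_los = {c: frame["los_days"].iloc[labels == c].mean() for c in clusters}
    lo, hi = min(mean_los.values()), max(mean_los.values())
    span = hi - lo
    rows = {}
    for c in clusters:
        mask = labels == c
        sub = frame.iloc[mask]
        vec = {"los_scaled": 0.0 if span == 0 else (mean_los[c] - lo) / span,
               "mortality": float(sub["mortality"].mean())}
        if include_vasoactive:
            vec["vasoactive"] = float(sub["vasoactive"].mean())
        counts = sub["diagnosis_category"].value_counts()
        for dx in diagnosis_vocabulary:
            vec[f"dx_{dx}"] = float(counts.get(dx, 0)) / len(sub)
        rows[c] = vec
    return ClusterProfile("outcome", pd.DataFrame(rows).T.sort_index())


def profile_latent(results, ds: MixedDataset, labels: np.ndarray) -> ClusterProfile:
    """Per-cluster mean of the frozen encoder's latent features."""
    labels = np.asarray(labels)
    z = results.encode(ds)
    rows = {int(c): z[labels == c].mean(axis=0) for c in np.unique(labels)}
    vectors = pd.DataFrame(rows).T.sort_index()
    vectors.columns = [f"z{i}" for i in range(z.shape[1])]
    return ClusterProfile("latent", vectors)


def gower_distance(a: pd.Series, b: pd.Series, ranges: pd.Series,
                   binary_cols: list[str]) -> float:
    """Gower dissimilarity between two profile rows, in [0, 1].

    Numeric components contribute |a - b| / range (0 where the pooled range
    is 0); binary-proportion components contribute |a - b| directly.
    """
    if not a.index.equals(b.index):
        raise ValueError("profiles must share the same variables")
    total = 0.0
    for var in a.index:
        diff = abs(float(a[var]) - float(b[var]))
        if var in binary_cols:
            total += diff
        else:
            r = float(ranges[var])
            total += 0.0 if r == 0 else diff / r
    return total / len(a.index)


def euclidean_distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def pooled_ranges(dev: ClusterProfile, ext: ClusterProfile) -> pd.Series:
    """Per-variable range over both cohorts' profile vectors, for Gower."""
    both = pd.concat([dev.vectors, ext.vectors])
    return both.max(axis=0) - both.min(axis=0)


def map_nonexclusive(external: ClusterProfile, development: ClusterProfile,
                     metric: str = "euclidean") -> dict[int, int]:
    """Each external cluster maps to its nearest development cluster;
    several external clusters may share a target.  Ties break to the lowest
    development cluster index."""
    if list(external.vectors.columns) != list(development.vectors.columns):
        raise ValueError("profiles are from different spaces")
    mapping = {}
    if metric == "gower":
        ranges = pooled_ranges(development, external)
    for e in external.clusters:
        best, best_d = None, np.inf
        for d in development.clusters:
            if metric == "gower":
                dist = gower_distance(external.vectors.loc[e],
                                      development.vectors.loc[d],
                                      ranges, external.binary_cols)
            else:
                dist = euclidean_distance(external.vectors.loc[e],
                                          development.vectors.loc[d])
            if dist < best_d - 1e-15:
                best, best_d = d, dist
        mapping[e] = best
    return mapping


class GeneralisabilityMap:
    """Three per-space mappings of external clusters onto development
    clusters, with identity-agreement counts."""

    SPACES = ("input", "outcome", "latent")

    def __init__(self, mappings: dict[str, dict[int, int]]):
        self.mappings = mappings

    def identity_agreement(self, space: str) -> int:
        return sum(1 for e, d in self.mappings[space].items() if e == d)

    def to_frame(self) -> pd.DataFrame:
        clusters = sorted(self.mappings["latent"])
        return pd.DataFrame(
            {f"{space}_target": [self.mappings[space][c] for c in clusters]
             for space in self.SPACES},
            index=pd.Index(clusters, name="external_cluster"))

    def summary(self) -> str:
        lines = ["Cluster generalisability map", "=" * 40, self.to_frame().to_string(), ""]
        for space in self.SPACES:
            k = len(self.mappings[space])
            lines.append(f"identity agreement ({space}): "
                         f"{self.identity_agreement(space)}/{k}")
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "cluster_mapping.csv")
        summary = {f"identity_agreement_{s}": self.identity_agreement(s)
                   for s in self.SPACES}
        summary["n_external_clusters"] = len(self.mappings["latent"])
        (outdir / "generalisability_summary.json").write_text(
            json.dumps(summary, indent=2))

    @staticmethod
    def read(outdir) -> "GeneralisabilityMap":
        from pathlib import Path
        df = pd.read_csv(Path(outdir) / "cluster_mapping.csv",
                         index_col="external_cluster")
        return GeneralisabilityMap(
            {s: {int(e): int(df.loc[e, f"{s}_target"]) for e in df.index}
             for s in GeneralisabilityMap.SPACES})


def generalisability_report(results, dev_ds: MixedDataset, dev_outcomes: OutcomeTable,
                            ext_ds: MixedDataset, ext_outcomes: OutcomeTable,
                            include_vasoactive: bool = False) -> GeneralisabilityMap:
    """Frozen application + three-space cluster mapping.

    Both datasets must already be scaled with the development cohort's
    statistics.  External labels come from the frozen model's ``predict``;
    development labels are the fitted labels recomputed the same way.
    """
    dev_labels, _ = results.predict(dev_ds)
    ext_labels, _ = results.predict(ext_ds)
    vocab = sorted(set(dev_outcomes.frame["diagnosis_category"].dropna())
                   | set(ext_outcomes.frame["diagnosis_category"].dropna()))
    dev_outcomes = dev_outcomes.aligned_to(dev_ds)
    ext_outcomes = ext_outcomes.aligned_to(ext_ds)
    mappings = {
        "input": map_nonexclusive(profile_input(ext_ds, ext_labels),
                                  profile_input(dev_ds, dev_labels), "gower"),
        "outcome": map_nonexclusive(
            profile_outcome(ext_outcomes, ext_labels, vocab, include_vasoactive),
            profile_outcome(dev_outcomes, dev_labels, vocab, include_vasoactive)),
        "latent": map_nonexclusive(profile_latent(results, ext_ds, ext_labels),
                                   profile_latent(results, dev_ds, dev_labels)),
    }
    return GeneralisabilityMap(mappings)
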