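"""Model/Results interface over the flow-typing analysis.

:class:`FlowTypeModel` holds a feature matrix (and optionally the normalized
beat waveforms it was derived from); :meth:`FlowTypeModel.fit` z-scores the
features, selects the number of clusters by the gap statistic, partitions the
data by spectral clustering, and — when waveforms are available — extracts
per-cluster exemplars, archetypes and subject-group composition.  The
returned :class:`FlowTypeResults` carries labels, the gap profile and the
cluster summaries, and can render a text summary or diagnostic plots.

Example
-------
>>> model = FlowTypeModel.from_beats(normalized_beats, n_boot=100)
>>> res = model.fit(seed=17)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archetypes import ClusterSummary, cluster_report
from .cluster import (
    DEFAULT_K_RANGE,
    DEFAULT_N_BOOT,
    GapProfile,
    ZScoredFeatures,
    gap_profile,
    select_k,
    spectral_cluster,
    zscore,
)
from .features import FEATURE_NAMES, FeatureMatrix, build_feature_matrix

__all__ = ["FlowTypeModel", "FlowTypeResults"]


def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


class FlowTypeModel:
    """Unsupervised flow-typing of beat waveforms from morphological features.

    Parameters
    ----------
    features : FeatureMatrix, DataFrame or (N, 3) array
        Columns are (onset, canopy, peaks).
    waveforms : (N, 100) array, optional
        The normalized beats the features came from; required for exemplar
        and archetype extraction.
    groups : sequence of str, optional
        Subject-group tag per waveform (LVO / IHC / OHC); required for
        composition reporting.  Taken from ``features.provenance`` when
        available.
    k_range : (kmin, kmax)
        Cluster counts compared by the gap statistic (default 2-7).
    n_boot : int
        Reference bootstrap iterations (default 1000).
    rbf_gamma : float
        RBF affinity scale on the z-scored features (default 1).
    """

    def __init__(
        self,
        features,
        waveforms: np.ndarray | None = None,
        groups=None,
        ids=None,
        k_range: tuple[int, int] = (DEFAULT_K_RANGE[0], DEFAULT_K_RANGE[-1]),
        n_boot: int = DEFAULT_N_BOOT,
        rbf_gamma: float = 1.0,
    ) -> None:
        if isinstance(features, FeatureMatrix):
            self.feature_values = features.values
            self.provenance = features.provenance
        elif isinstance(features, pd.DataFrame):
            self.feature_values = features[list(FEATURE_NAMES)].to_numpy(float)
            self.provenance = features.drop(columns=list(FEATURE_NAMES))
        else:
            self.feature_values = np.asarray(features, dtype=float)
            self.provenance = pd.DataFrame(index=range(len(self.feature_values)))
        if self.feature_values.ndim != 2 or self.feature_values.shape[1] != 3:
            raise ValueError("features must be N x 3 (onset, canopy, peaks)")

        self.waveforms = None if waveforms is None else np.asarray(waveforms, float)
        if groups is None and "group" in self.provenance.columns:
            groups = self.provenance["group"].tolist()
        self.groups = list(groups) if groups is not None else None
        if ids is None and "subject_id" in self.provenance.columns:
            ids = [
                f"{s}|{h}|{d:g}|{i}"
                for i, (s, h, d) in enumerate(
                    zip(
                        self.provenance["subject_id"],
                        self.provenance.get("hemisphere", [""] * len(self.provenance)),
                        self.provenance.get("depth_mm", [0.0] * len(self.provenance)),
                    )
                )
            ]
        self.ids = list(ids) if ids is not None else list(range(len(self.feature_values)))

        if not (2 <= k_range[0] <= k_range[1]):
            raise ValueError("k_range must satisfy 2 <= kmin <= kmax")
        self.k_range = tuple(range(k_range[0], k_range[1] + 1))
        self.n_boot = int(n_boot)
        self.rbf_gamma = float(rbf_gamma)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_beats(cls, beats, pseudo_threshold: float | None = None, **kwargs):
        """Build the model from normalized beats (features are computed)."""
        from .features import PSEUDO_PEAK_THRESHOLD

        thr = PSEUDO_PEAK_THRESHOLD if pseudo_threshold is None else pseudo_threshold
        fm = build_feature_matrix(beats, threshold=thr)
        W = np.stack([b.samples for b in beats])
        return cls(fm, waveforms=W, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        """Build the model from a DataFrame with onset/canopy/peaks columns."""
        return cls(df, **kwargs)

    # -- estimation -------------------------------------------------------

    def fit(self, seed: int | None = None, k: int | None = None) -> "FlowTypeResults":
        """Estimate the partition.

        When ``k`` is None the cluster count is selected by the gap statistic
        over ``self.k_range``; otherwise the data are clustered at the given
        k and no gap profile is computed.  All randomness derives from
        ``seed``.
        """
        s_gap, s_cluster = _child_seeds(seed, 2)
        z = zscore(self.feature_values, column_names=FEATURE_NAMES)

        profile = None
        elbow_found = True
        if k is None:
            profile = gap_profile(
                z.values,
                k_range=self.k_range,
                n_boot=self.n_boot,
                seed=s_gap,
                gamma=self.rbf_gamma,
            )
            sel = select_k(profile)
            k, elbow_found = sel.k, sel.elbow_found

        labels = spectral_cluster(z.values, k, gamma=self.rbf_gamma, seed=s_cluster)

        clusters = None
        if self.waveforms is not None and self.groups is not None:
            clusters = cluster_report(self.waveforms, labels, self.groups, self.ids)

        return FlowTypeResults(
            model=self,
            k=int(k),
            elbow_found=elbow_found,
            labels=labels,
            zscored=z,
            gap=profile,
            clusters=clusters,
            seed=seed,
        )


@dataclass
class FlowTypeResults:
    """Fitted flow-typing partition with diagnostics."""

    model: FlowTypeModel
    k: int
    elbow_found: bool
    labels: np.ndarray
    zscored: ZScoredFeatures
    gap: GapProfile | None = None
    clusters: list[ClusterSummary] | None = None
    seed: int | None = None

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def composition_table(self) -> pd.DataFrame:
        """Per-cluster size and group percentages as a DataFrame."""
        if self.clusters is None:
            raise ValueError("no cluster report (waveforms/groups unavailable)")
        rows = []
        for c in self.clusters:
            row = {"cluster": c.cluster, "size": c.size}
            row.update({f"{g}_pct": p for g, p in c.percent.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Flow-type clustering results",
            "=" * 60,
            f"observations:       {len(self.labels)}",
            f"selected clusters:  {self.k}"
            + ("" if self.elbow_found else "  (no elbow; largest k reported)"),
            f"cluster sizes:      {self.cluster_sizes.tolist()}",
        ]
        if self.gap is not None:
            lines += [
                "",
                "  k    logW    E[logW]     gap       S",
                "  " + "-" * 42,
            ]
            for j, kk in enumerate(self.gap.k_values):
                lines.append(
                    f"  {kk}  {self.gap.log_w[j]:8.4f}  {self.gap.e_log_w[j]:8.4f}"
                    f"  {self.gap.gap[j]:8.4f}  {self.gap.s[j]:7.4f}"
                )
        if self.clusters is not None:
            lines += ["", "cluster composition (% of member waveforms):"]
            for c in self.clusters:
                pct = ", ".join(f"{g} {p}%" for g, p in c.percent.items())
                lines.append(
                    f"  cluster {c.cluster}: n={c.size:<4d} {pct}"
                    f"  exemplar={c.exemplar_id}"
                )
        return "\n".join(lines)

    # -- plots ------------------------------------------------------------

    def plot_gap(self, ax=None):
        """Gap statistic (with +-S error bars) versus cluster count."""
        import matplotlib.pyplot as plt

        if self.gap is None:
            raise ValueError("fit was run with fixed k; no gap profile")
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.gap.k_values, self.gap.gap, yerr=self.gap.s, marker="o")
        ax.axvline(self.k, color="grey", ls="--", lw=1)
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("gap statistic $G_k$")
        return ax

    def plot_archetypes(self, axes=None):
        """One panel per cluster showing the archetype waveform."""
        import matplotlib.pyplot as plt

        if self.clusters is None:
            raise ValueError("no cluster report (waveforms unavailable)")
        n = len(self.clusters)
        if axes is None:
            _, axes = plt.subplots(1, n, figsize=(3 * n, 2.5), sharey=True)
            axes = np.atleast_1d(axes)
        for ax, c in zip(axes, self.clusters):
            ax.plot(c.archetype)
            ax.set_title(f"cluster {c.cluster} (n={c.size})")
            ax.set_xlabel("normalized time")
        axes[0].set_ylabel("normalized velocity")
        return axes

    def to_json_dict(self) -> dict:
        """JSON-serializable dump of labels, selection and gap profile."""
        out = {
            "k_selected": self.k,
            "elbow_found": self.elbow_found,
            "seed": self.seed,
            "labels": {str(i): int(l) for i, l in zip(self.model.ids, self.labels)},
        }
        if self.gap is not None:
            out["gap_profile"] = self.gap.to_dict()
        if self.clusters is not None:
            out["clusters"] = [c.to_dict() for c in self.clusters]
        return out
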