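"""2-D manifold projections and quantitative cluster-separability scores.

The study's evidence is the visual separability of UMAP scatter plots; here
each projection is also scored quantitatively with the silhouette
coefficient and a between/within centroid-distance ratio, computed both in
the 2-D embedding (what a reader of the scatter plots judges) and in the
original feature space (a projection-free robustness check).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .filters import apply_variant, filter_bank
from .pairing import split_subjects, verification_pairs
from .pipeline import ExperimentConfig, materialize_records
from .spectral import feature_columns, feature_matrix


@dataclasses.dataclass
class ProjectionParams:
    """UMAP hyperparameters (the library's documented defaults)."""

    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"


@dataclasses.dataclass
class EmbeddingResult:
    """2-D coordinates with labels, fold membership and separability scores."""

    coordinates: np.ndarray
    labels: np.ndarray
    split: np.ndarray
    params: ProjectionParams
    seed: int
    scores: dict

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")
        n = self.coordinates.shape[0]
        if len(self.labels) != n or len(self.split) != n:
            raise ValueError("labels/split must tag every point")


def separability_score(points: np.ndarray, labels) -> dict:
    """Silhouette coefficient and between/within centroid-distance ratio.

    Singleton classes are excluded with a warning (the silhouette is
    undefined for them).  Higher values of both scores mean more separable
    label clusters.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    singles = classes[counts < 2]
    if singles.size:
        warnings.warn(
            f"excluding singleton class(es) {singles.tolist()} from scoring",
            stacklevel=2,
        )
        keep = ~np.isin(labels, singles)
        points, labels = points[keep], labels[keep]
        classes = classes[counts >= 2]
    if classes.size < 2:
        raise ValueError("scoring needs at least two classes with >= 2 points")
    centroids = np.vstack([points[labels == c].mean(axis=0) for c in classes])
    within = float(
        np.mean(
            [
                np.linalg.norm(points[labels == c] - centroids[i], axis=1).mean()
                for i, c in enumerate(classes)
            ]
        )
    )
    between = float(np.mean(pdist(centroids)))
    return {
        "silhouette": float(silhouette_score(points, labels)),
        "centroid_ratio": between / max(within, 1e-12),
    }


def _umap_module():
    import umap  # deferred: numba-backed import is expensive

    return umap


def project_unsupervised(
    features: np.ndarray,
    labels=None,
    params: ProjectionParams | None = None,
    seed: int = 42,
) -> EmbeddingResult:
    """Neighborhood-preserving 2-D projection of a feature matrix."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 10 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 10 points and >= 2 features")
    p = params or ProjectionParams()
    if x.shape[0] <= p.n_neighbors:
        raise ValueError(
            f"{x.shape[0]} points is not more than the neighborhood size "
            f"{p.n_neighbors}"
        )
    umap = _umap_module()
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=p.n_neighbors,
        min_dist=p.min_dist,
        metric=p.metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(x)
    labels_arr = (
        np.asarray(labels) if labels is not None else np.zeros(x.shape[0], dtype=int)
    )
    scores = {"all": separability_score(coords, labels_arr)} if labels is not None else {}
    return EmbeddingResult(
        coordinates=coords,
        labels=labels_arr,
        split=np.full(x.shape[0], "all", dtype=object),
        params=p,
        seed=seed,
        scores=scores,
    )


def project_supervised(
    train_features: np.ndarray,
    train_labels,
    test_features: np.ndarray | None = None,
    test_labels=None,
    params: ProjectionParams | None = None,
    seed: int = 42,
) -> EmbeddingResult:
    """Label-aware projection fitted on train, applied unchanged to test.

    Test points are placed by the fitted transform only — no refit — which
    is what makes the train/test score comparison a generalization check.
    """
    xtr = np.asarray(train_features, dtype=float)
    ytr = np.asarray(train_labels)
    if xtr.ndim != 2 or xtr.shape[0] != ytr.shape[0]:
        raise ValueError("train label/feature length mismatch")
    p = params or ProjectionParams()
    if xtr.shape[0] <= p.n_neighbors:
        raise ValueError("fewer train points than the neighborhood size")
    codes, _ = pd.factorize(ytr)
    umap = _umap_module()
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=p.n_neighbors,
        min_dist=p.min_dist,
        metric=p.metric,
        random_state=seed,
    )
    reducer.fit(xtr, y=codes)
    coords = [reducer.embedding_]
    labels = [ytr]
    split = [np.full(xtr.shape[0], "train", dtype=object)]
    scores = {"train": separability_score(reducer.embedding_, ytr)}
    if test_features is not None:
        xte = np.asarray(test_features, dtype=float)
        cte = reducer.transform(xte)
        coords.append(cte)
        split.append(np.full(xte.shape[0], "test", dtype=object))
        if test_labels is not None:
            yte = np.asarray(test_labels)
            if yte.shape[0] != xte.shape[0]:
                raise ValueError("test label/feature length mismatch")
            labels.append(yte)
            scores["test"] = separability_score(cte, yte)
        else:
            labels.append(np.full(xte.shape[0], "?", dtype=object))
    return EmbeddingResult(
        coordinates=np.vstack(coords),
        labels=np.concatenate(labels),
        split=np.concatenate(split),
        params=p,
        seed=seed,
        scores=scores,
    )


def plot_embedding(result: EmbeddingResult, path, title: str | None = None) -> Path:
    """Scatter of a 2-D embedding, colored by label, marker shape by fold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    classes = pd.unique(result.labels)
    cmap = plt.get_cmap("tab20" if len(classes) > 10 else "tab10")
    markers = {"all": "o", "train": "o", "test": "^"}
    for fold in pd.unique(result.split):
        for ci, c in enumerate(classes):
            sel = (result.labels == c) & (result.split == fold)
            if not np.any(sel):
                continue
            ax.scatter(
                result.coordinates[sel, 0],
                result.coordinates[sel, 1],
                s=8,
                alpha=0.7,
                color=cmap(ci % cmap.N),
                marker=markers.get(fold, "o"),
                label=f"{c} ({fold})" if len(classes) <= 6 else None,
            )
    if len(classes) <= 6:
        ax.legend(fontsize=7, markerscale=2)
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


REPORT_COLUMNS = (
    "source",
    "filter",
    "mode",
    "fold",
    "n_points",
    "silhouette",
    "centroid_ratio",
    "feature_silhouette",
)


def run_experiment(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Run the (source x filter x mode) grid and score every cell.

    Returns one row per (source, filter, mode, fold) with embedding-space
    and feature-space separability; writes ``scores.csv``, a markdown
    summary and per-cell scatter plots when ``out_dir`` is given.  The run
    is fully reproducible under ``config.seed``.
    """
    records = materialize_records(config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    params = ProjectionParams(
        n_neighbors=config.n_neighbors, min_dist=config.min_dist, metric=config.metric
    )
    rows = []
    for source_name, _kind in config.sources:
        recs = [r for r in records if r.source_name == source_name]
        if not recs:
            raise ValueError(f"no records for source {source_name!r}")
        days = {r.day for r in recs}
        if "verification" in config.modes and days < {1, 2}:
            raise ValueError(
                f"source {source_name!r} lacks both acquisition days: {sorted(days)}"
            )
        known = filter_bank(recs[0].sampling_rate)
        for variant in config.filter_variants:
            if variant not in known:
                raise ValueError(f"unknown filter variant {variant!r}")
            filtered = [apply_variant(r, variant) for r in recs]
            feats = feature_matrix(filtered, feature=config.feature_kind)
            fcols = feature_columns(feats)
            x = feats[fcols].to_numpy(dtype=float)
            subjects = feats["subject_id"].to_numpy()
            if "identification" in config.modes:
                emb = project_unsupervised(
                    x, labels=subjects, params=params, seed=config.seed
                )
                feat_scores = separability_score(x, subjects)
                cell = emb.scores["all"]
                rows.append(
                    dict(
                        source=source_name,
                        filter=variant,
                        mode="identification",
                        fold="all",
                        n_points=len(subjects),
                        silhouette=cell["silhouette"],
                        centroid_ratio=cell["centroid_ratio"],
                        feature_silhouette=feat_scores["silhouette"],
                    )
                )
                if out_dir is not None:
                    plot_embedding(
                        emb,
                        out_dir / f"{source_name}_{variant}_identification.png",
                        title=f"{source_name} / {variant} / identification",
                    )
            if "verification" in config.modes:
                ids = sorted(set(subjects.tolist()))
                n_train = config.n_train or len(ids) // 2 + len(ids) % 2
                split = split_subjects(ids, n_train, seed=config.seed)
                xp, y, fold, _meta = verification_pairs(
                    feats, split, n_per_class=config.pairs_per_class, seed=config.seed
                )
                tr, te = fold == "train", fold == "test"
                emb = project_supervised(
                    xp[tr], y[tr], xp[te], y[te], params=params, seed=config.seed
                )
                for fname, mask in (("train", tr), ("test", te)):
                    cell = emb.scores[fname]
                    rows.append(
                        dict(
                            source=source_name,
                            filter=variant,
                            mode="verification",
                            fold=fname,
                            n_points=int(mask.sum()),
                            silhouette=cell["silhouette"],
                            centroid_ratio=cell["centroid_ratio"],
                            feature_silhouette=separability_score(xp[mask], y[mask])[
                                "silhouette"
                            ],
                        )
                    )
                if out_dir is not None:
                    plot_embedding(
                        emb,
                        out_dir / f"{source_name}_{variant}_verification.png",
                        title=f"{source_name} / {variant} / verification",
                    )
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if out_dir is not None:
        report.to_csv(out_dir / "scores.csv", index=False, float_format="%.6f")
        with open(out_dir / "summary.md", "w", encoding="utf-8") as fh:
            fh.write("# Separability report\n\n")
            fh.write(report.to_markdown(index=False, floatfmt=".3f"))
            fh.write("\n")
    return report
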