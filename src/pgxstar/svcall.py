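"""Structural-variant classification from binned copy-number profiles.

Pharmacogene structural variants (whole-gene deletions, duplications,
higher-order multiplications, and gene-pseudogene hybrids) leave
near-piecewise-constant signatures in a sample's copy-number profile: a
whole-gene deletion drops the track to 1 (het) or 0 (hom), a duplication
lifts it to 3, a tandem multiplication to 4, and a hybrid produces a step
at the fusion breakpoint mirrored in the captured pseudogene.  Each gene
declares a closed set of such configurations; a sample's binned profile is
classified with a one-vs-rest SVM (RBF kernel), with an *Indeterminate* escape
hatch for profiles that match no trained configuration (novel SVs).

The per-gene class registry and the per-haplotype copy-number templates
used both here and by the simulator are defined in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .catalog import GeneDefinition, parse_copy_suffix
from .covdepth import CopyNumberProfile
from .errors import ClassifierError

__all__ = [
    "HAPLOTYPE_CN_TEMPLATES",
    "SV_CLASSES",
    "CNFeatureVector",
    "SVCall",
    "SVClassifier",
    "haplotype_cn_track",
    "diplotype_cn_track",
    "sv_class_for_allele",
    "expected_sv_class",
    "featurize_profile",
    "train_sv_classifier",
    "classify_sv",
    "save_classifier",
    "load_classifier",
]

# ---------------------------------------------------------------------------
# Copy-number templates.
#
# A haplotype template gives, as piecewise segments over the *fractional*
# gene span [0, 1), the number of gene copies that haplotype contributes,
# plus any extra pseudogene copies (hybrids convert gene material into
# pseudogene-like material past the fusion breakpoint).  A plain haplotype
# contributes 1 gene copy everywhere and 1 pseudogene copy (when the gene
# has a captured pseudogene).

_WHOLE = ((0.0, 1.0, 1),)

# (gene, allele) -> {"gene": segments, "pseudo_extra": segments}
HAPLOTYPE_CN_TEMPLATES: dict[tuple[str, str], dict] = {
    ("CYP2D6", "*5"): {"gene": ((0.0, 1.0, 0),), "pseudo_extra": ()},
    ("CYP2D6", "*36+*10"): {
        "gene": ((0.0, 0.8, 2), (0.8, 1.0, 1)),
        "pseudo_extra": ((0.8, 1.0, 1),),
    },
    ("CYP2D6", "*36x2+*10"): {
        "gene": ((0.0, 0.8, 3), (0.8, 1.0, 1)),
        "pseudo_extra": ((0.8, 1.0, 2),),
    },
    ("CYP2D6", "*68+*4"): {
        "gene": ((0.0, 0.3, 2), (0.3, 1.0, 1)),
        "pseudo_extra": ((0.3, 1.0, 1),),
    },
    ("CYP2B6", "*29"): {
        "gene": ((0.0, 0.6, 0), (0.6, 1.0, 1)),
        "pseudo_extra": ((0.0, 0.6, 1),),
    },
    ("CYP2E1", "*S1"): {"gene": ((0.0, 0.5, 2), (0.5, 1.0, 1)), "pseudo_extra": ()},
    ("SLC22A2", "*S2"): {"gene": ((0.0, 0.5, 0), (0.5, 1.0, 1)), "pseudo_extra": ()},
}

# Per-gene SV class sets with a canonical carrier diplotype for each class.
SV_CLASSES: dict[str, dict[str, tuple[str, str]]] = {
    "CYP2D6": {
        "normal": ("*1", "*1"),
        "whole_del": ("*1", "*5"),
        "whole_dup": ("*1", "*2x2"),
        "hyb_36_10": ("*1", "*36+*10"),
        "hyb_36x2_10": ("*41", "*36x2+*10"),
        "hyb_68_4": ("*1", "*68+*4"),
    },
    "CYP2E1": {
        "normal": ("*1", "*1"),
        "dup": ("*1", "*7x2"),
        "mult": ("*1", "*7x3"),
        "partial_dup": ("*1", "*S1"),
    },
    "GSTT1": {"normal": ("*A", "*A"), "del_het": ("*A", "*0"), "del_hom": ("*0", "*0")},
    "GSTM1": {
        "normal": ("*A", "*A"),
        "del_het": ("*A", "*0"),
        "del_hom": ("*0", "*0"),
        "dup": ("*A", "*Ax2"),
    },
    "UGT2B17": {"normal": ("*1", "*1"), "del_het": ("*1", "*2"), "del_hom": ("*2", "*2")},
    "UGT2B15": {"normal": ("*1", "*1"), "del_het": ("*1", "*S1")},
    "SLC22A2": {"normal": ("*1", "*1"), "del_S1": ("*1", "*S1"), "del_S2": ("*1", "*S2")},
    "CYP2A6": {"normal": ("*1", "*1"), "del_het": ("*1", "*4"), "dup": ("*1", "*1x2")},
    "CYP2B6": {"normal": ("*1", "*1"), "hyb_29": ("*1", "*29")},
}


def _segments_value(segments, frac: float, default: int) -> int:
    for f0, f1, v in segments:
        if f0 <= frac < f1 or (frac == 1.0 and f1 == 1.0):
            return v
    return default


def haplotype_cn_track(gene: str, allele: str, gene_fracs: np.ndarray, pseudo_fracs: np.ndarray | None):
    """Per-position (gene_copies, pseudo_copies) contributed by one haplotype.

    Deletion / duplication / multiplication alleles scale the whole-gene
    copy count via their ``xN`` suffix or deletion tag; hybrid and partial
    alleles use their registered piecewise template.
    """
    key = (gene, allele)
    if key in HAPLOTYPE_CN_TEMPLATES:
        tmpl = HAPLOTYPE_CN_TEMPLATES[key]
        g = np.array([_segments_value(tmpl["gene"], f, 1) for f in gene_fracs], dtype=float)
        p = None
        if pseudo_fracs is not None:
            p = 1.0 + np.array(
                [_segments_value(tmpl["pseudo_extra"], f, 0) for f in pseudo_fracs], dtype=float
            )
        return g, p
    base, copies = parse_copy_suffix(allele)
    # deletion alleles are registered per gene via SV_CLASSES canonical names
    if allele in _deletion_alleles(gene):
        copies = 0
    g = np.full(len(gene_fracs), float(copies))
    p = np.ones(len(pseudo_fracs)) if pseudo_fracs is not None else None
    return g, p


def _deletion_alleles(gene: str) -> set[str]:
    out = set()
    for cls, (a1, a2) in SV_CLASSES.get(gene, {}).items():
        if cls.startswith("del") or cls == "whole_del":
            out.update(a for a in (a1, a2))
    # deletion classes pair the deleted allele with the reference; strip the reference
    normals = set(SV_CLASSES.get(gene, {}).get("normal", ()))
    return out - normals if out else out


def diplotype_cn_track(gene: str, diplotype: tuple[str, str], gene_fracs, pseudo_fracs=None):
    """Total (gene, pseudogene) copy-number track for a diplotype."""
    g1, p1 = haplotype_cn_track(gene, diplotype[0], gene_fracs, pseudo_fracs)
    g2, p2 = haplotype_cn_track(gene, diplotype[1], gene_fracs, pseudo_fracs)
    g = g1 + g2
    p = (p1 + p2) if p1 is not None else None
    return g, p


def sv_class_for_allele(gene: str, allele: str) -> str | None:
    """The SV class produced by carrying ``allele`` against a normal partner.

    Alleles sharing a copy-number configuration share a class (e.g. every
    whole-gene duplication allele maps to the same duplication class).
    """
    registry = SV_CLASSES.get(gene)
    if registry is None:
        return None
    for cls, pair in registry.items():
        if cls != "normal" and allele in pair:
            return cls
    reference = registry["normal"][0]
    return expected_sv_class(gene, (reference, allele))


def expected_sv_class(gene: str, diplotype: tuple[str, str], n_points: int = 50) -> str:
    """The registered class whose CN template matches a diplotype's track.

    Used to label simulated truth: e.g. both ``*7/*7x3`` and ``*7x2/*7x2``
    produce the whole-gene copy-4 plateau and map to the same class.
    """
    if gene not in SV_CLASSES:
        return "normal"
    fr = np.linspace(0, 1, n_points, endpoint=False)
    g, p = diplotype_cn_track(gene, diplotype, fr, fr)
    best, best_err = None, math.inf
    for cls, pair in SV_CLASSES[gene].items():
        cg, cp = diplotype_cn_track(gene, pair, fr, fr)
        err = float(np.abs(g - cg).mean())
        if p is not None and cp is not None:
            err += float(np.abs(p - cp).mean())
        if err < best_err:
            best, best_err = cls, err
    return best


# ---------------------------------------------------------------------------
# featurization


@dataclass
class CNFeatureVector:
    """Mean copy number per genomic bin over the gene (+ pseudogene) span."""

    gene: str
    values: np.ndarray
    bin_bp: int
    sample: str | None = None


def _bin_means(positions: np.ndarray, values: np.ndarray, start: int, end: int, bin_bp: int) -> np.ndarray:
    n_bins = math.ceil((end - start + 1) / bin_bp)
    out = np.full(n_bins, np.nan)
    sel = (positions >= start) & (positions <= end)
    pos, val = positions[sel], values[sel]
    idx = ((pos - start) // bin_bp).astype(int)
    for b in range(n_bins):
        v = val[idx == b]
        v = v[~np.isnan(v)]
        if len(v):
            out[b] = v.mean()
    return out


def _impute_gaps(vec: np.ndarray) -> np.ndarray:
    """Fill empty/masked bins from the mean of the nearest non-empty flanks."""
    out = vec.copy()
    nan = np.isnan(out)
    if nan.all():
        raise ClassifierError("all feature bins are empty")
    idx = np.arange(len(out))
    good = idx[~nan]
    for i in idx[nan]:
        left = good[good < i]
        right = good[good > i]
        neighbors = []
        if len(left):
            neighbors.append(out[left[-1]])
        if len(right):
            neighbors.append(out[right[0]])
        out[i] = float(np.mean(neighbors))
    return out


def featurize_profile(p: CopyNumberProfile, gene: GeneDefinition, bin_bp: int = 500) -> CNFeatureVector:
    """Bin a copy-number profile into fixed-length mean-CN features.

    Bins span the gene region followed by the captured pseudogene region (if
    any).  Masked positions are ignored inside bins; bins left empty are
    imputed from their flanking bins.
    """
    if bin_bp <= 0:
        raise ClassifierError("bin_bp must be positive")
    parts = []
    for interval in (gene.region, gene.pseudogene_region):
        if interval is None:
            continue
        if interval[1] - interval[0] + 1 < bin_bp:
            raise ClassifierError(f"{gene.symbol}: region shorter than one bin")
        parts.append(_bin_means(p.positions, p.values, interval[0], interval[1], bin_bp))
    vec = _impute_gaps(np.concatenate(parts))
    return CNFeatureVector(gene=gene.symbol, values=vec, bin_bp=bin_bp, sample=p.sample)


# ---------------------------------------------------------------------------
# classifier


@dataclass
class SVCall:
    """A per-sample/gene SV classification with decision scores."""

    gene: str
    label: str
    scores: dict[str, float]
    indeterminate: bool = False
    reason: str | None = None


@dataclass
class SVClassifier:
    """One-vs-rest SVM over binned CN features with novelty calibration."""

    gene: str
    classes: list[str]
    model: OneVsRestClassifier
    centroids: dict[str, np.ndarray]
    scales: dict[str, np.ndarray]
    distance_cutoffs: dict[str, float]
    margin_cutoffs: dict[str, float]
    n_features: int
    training_accuracy: float
    version: str = "1"

    def distance(self, x: np.ndarray, cls: str) -> float:
        """Root-mean-square standardized distance to a class centroid."""
        z = (x - self.centroids[cls]) / self.scales[cls]
        return float(np.sqrt(np.mean(z**2)))


def train_sv_classifier(features: list[CNFeatureVector], labels: list[str], seed: int = 0) -> SVClassifier:
    """Train a one-vs-rest SVM (RBF kernel) on labeled CN feature vectors.

    Requires at least two classes and three examples per class.  The
    Indeterminate escape hatch is calibrated on the training set: per
    predicted class, a floor on the top one-vs-rest margin and a ceiling on
    the standardized distance to the class centroid (99.5th percentile with
    a safety factor).  Calibrating the margin floor per class, rather than
    thresholding at zero, is necessary because interior classes of a
    one-vs-rest ensemble legitimately sit at negative margins.
    """
    if len(features) != len(labels):
        raise ClassifierError("features and labels differ in length")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ClassifierError("need at least two SV classes to train")
    for cls in classes:
        if labels.count(cls) < 3:
            raise ClassifierError(f"class {cls!r} has fewer than 3 training examples")
    X = np.vstack([f.values for f in features])
    y = np.asarray(labels)
    model = OneVsRestClassifier(SVC(kernel="rbf", gamma="scale", random_state=seed))
    model.fit(X, y)
    centroids = {cls: X[y == cls].mean(axis=0) for cls in classes}
    scales = {
        cls: np.maximum(X[y == cls].std(axis=0), 0.15) for cls in classes
    }
    clf = SVClassifier(
        gene=features[0].gene,
        classes=classes,
        model=model,
        centroids=centroids,
        scales=scales,
        distance_cutoffs={},
        margin_cutoffs={},
        n_features=X.shape[1],
        training_accuracy=0.0,
    )
    for cls in classes:
        d = np.array([clf.distance(x, cls) for x in X[y == cls]])
        clf.distance_cutoffs[cls] = max(float(np.quantile(d, 0.995)) * 2.0, 1.5)
    scores = _decision_scores(model, X, classes)
    for cls in classes:
        own = scores[y == cls][:, classes.index(cls)]
        clf.margin_cutoffs[cls] = float(own.min()) - 1.0
    clf.training_accuracy = float((model.predict(X) == y).mean())
    return clf


def _decision_scores(model: OneVsRestClassifier, X: np.ndarray, classes: list[str]) -> np.ndarray:
    raw = model.decision_function(X)
    if raw.ndim == 1:  # binary special case: one margin column
        order = list(model.classes_)
        out = np.zeros((len(X), 2))
        out[:, order.index(model.classes_[1])] = raw
        out[:, order.index(model.classes_[0])] = -raw
        return out[:, [list(model.classes_).index(c) for c in classes]]
    order = list(model.classes_)
    return raw[:, [order.index(c) for c in classes]]


def classify_sv(m: SVClassifier, f: CNFeatureVector) -> SVCall:
    """Classify one feature vector; fall to Indeterminate for novel profiles.

    Indeterminate when the top one-vs-rest decision score falls below the
    winning class's calibrated margin floor, or when the standardized
    distance to that class's centroid exceeds its calibrated ceiling --
    either signals a profile unlike anything in the trained class set
    (e.g. a novel partial deletion or an unregistered hybrid).
    """
    if len(f.values) != m.n_features:
        raise ClassifierError(
            f"feature length {len(f.values)} != training length {m.n_features}"
        )
    x = f.values.reshape(1, -1)
    score_row = _decision_scores(m.model, x, m.classes)[0]
    scores = dict(zip(m.classes, (float(v) for v in score_row)))
    label = max(scores, key=scores.get)
    dist = m.distance(f.values, label)
    indet = False
    reason = None
    if scores[label] < m.margin_cutoffs[label]:
        indet, reason = True, "no class asserted (top margin below calibrated floor)"
    elif dist > m.distance_cutoffs[label]:
        indet, reason = True, "profile far from all trained class centroids"
    return SVCall(
        gene=m.gene,
        label=label if not indet else "indeterminate",
        scores=scores,
        indeterminate=indet,
        reason=reason,
    )


def save_classifier(m: SVClassifier, path) -> None:
    """Serialize a classifier bundle (versioned)."""
    joblib.dump({"format_version": m.version, "classifier": m}, path)


def load_classifier(path) -> SVClassifier:
    bundle = joblib.load(path)
    return bundle["classifier"]
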