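"""Fluorescent-barcode color classification of segmented nuclei.

Cells are barcoded with six additive combinations of red, green and blue
nuclear fluorescent proteins (R, G, B, RG, RB, GB).  Each segmented nucleus
is assigned one of the six color classes or TRASH (debris, fragments,
imaging artifacts) by a decision tree trained on manually labeled examples,
exactly one class per nucleus.  Classification features are dominated by
scale-free channel fractions so that expression-level differences between
cells do not move class boundaries.

A rule-based fallback (a channel is "on" when it carries more than a
quarter of the summed signal) supports label-free operation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

CHANNELS = ("r", "g", "b")
CLASSES = ("R", "G", "B", "RG", "RB", "GB", "TRASH")

#: feature names in canonical order
FEATURE_SPEC = (
    "mean_r", "mean_g", "mean_b",
    "frac_r", "frac_g", "frac_b",
    "log_total", "area", "circularity",
)

MODEL_FORMAT_VERSION = 1


def extract_color_features(records: pd.DataFrame) -> np.ndarray:
    """Feature matrix (n, len(FEATURE_SPEC)) from a nucleus table.

    Features per nucleus: per-channel mean intensity (total / area),
    channel fractions (channel / sum over channels), log total intensity,
    area and circularity.  Nuclei with zero total intensity across all
    channels get fractions of 1/3 each and are flagged in
    ``result_flags`` (returned via ``.attrs`` when input is a DataFrame).
    """
    needed = [f"intensity_{c}" for c in CHANNELS]
    core = [f"core_intensity_{c}" for c in CHANNELS]
    if all(c in records.columns for c in core):
        needed = core          # core intensities resist neighbour bleed
    for col in needed + ["area", "circularity"]:
        if col not in records.columns:
            raise ValueError(f"nucleus table lacks column {col}")
    inten = records[needed].to_numpy(dtype=np.float64)
    area = records["area"].to_numpy(dtype=np.float64)
    circ = records["circularity"].to_numpy(dtype=np.float64)
    total = inten.sum(axis=1)
    zero = total <= 0
    safe_total = np.where(zero, 1.0, total)
    fracs = inten / safe_total[:, None]
    fracs[zero] = 1.0 / 3.0
    means = inten / np.maximum(area, 1.0)[:, None]
    log_total = np.log1p(np.maximum(total, 0.0))
    feats = np.column_stack([means, fracs, log_total, area, circ])
    return feats


@dataclass
class ColorModel:
    """A trained decision tree serialized as explicit decision rules.

    The tree is stored as parallel arrays (children, split feature, split
    threshold, leaf class) so that a saved model reloads with bit-identical
    predictions and without depending on the training library's pickle
    format.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray          # index into classes, valid at leaves
    classes: tuple[str, ...]
    feature_spec: tuple[str, ...] = FEATURE_SPEC
    training_accuracy: float = float("nan")

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Class labels for a feature matrix, by explicit tree traversal."""
        features = np.asarray(features, dtype=np.float64)
        n = features.shape[0]
        node = np.zeros(n, dtype=np.int64)
        active = np.arange(n)
        while active.size:
            cur = node[active]
            is_leaf = self.children_left[cur] == -1
            active = active[~is_leaf]
            if not active.size:
                break
            cur = node[active]
            go_left = (features[active, self.feature[cur]]
                       <= self.threshold[cur])
            node[active] = np.where(go_left, self.children_left[cur],
                                    self.children_right[cur])
        return np.asarray(self.classes, dtype=object)[self.leaf_class[node]]

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "classes": list(self.classes),
            "feature_spec": list(self.feature_spec),
            "training_accuracy": self.training_accuracy,
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ColorModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported color model format version")
        return cls(
            children_left=np.asarray(payload["children_left"], dtype=np.int64),
            children_right=np.asarray(payload["children_right"], dtype=np.int64),
            feature=np.asarray(payload["feature"], dtype=np.int64),
            threshold=np.asarray(payload["threshold"], dtype=np.float64),
            leaf_class=np.asarray(payload["leaf_class"], dtype=np.int64),
            classes=tuple(payload["classes"]),
            feature_spec=tuple(payload["feature_spec"]),
            training_accuracy=float(payload["training_accuracy"]),
        )


def train_color_model(features: np.ndarray, labels: np.ndarray,
                      feature_spec: tuple[str, ...] = FEATURE_SPEC,
                      random_state: int = 0) -> ColorModel:
    """Fit a decision tree (Gini impurity, unlimited depth) on labeled data.

    Raises on single-class input; warns when any present class has fewer
    than 10 examples.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    present, counts = np.unique(labels, return_counts=True)
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if (counts < 10).any():
        few = [str(c) for c, n in zip(present, counts) if n < 10]
        warnings.warn(f"classes with fewer than 10 training examples: {few}")
    if features.shape[1] != len(feature_spec):
        raise ValueError("feature matrix width does not match feature_spec")
    tree = DecisionTreeClassifier(criterion="gini", random_state=random_state)
    tree.fit(features, labels)
    t = tree.tree_
    leaf_class = np.argmax(t.value[:, 0, :], axis=1)
    classes = tuple(str(c) for c in tree.classes_)
    acc = float((tree.predict(features) == labels).mean())
    return ColorModel(
        children_left=t.children_left.astype(np.int64),
        children_right=t.children_right.astype(np.int64),
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.astype(np.float64),
        leaf_class=leaf_class.astype(np.int64),
        classes=classes,
        feature_spec=tuple(feature_spec),
        training_accuracy=acc,
    )


def classify_nuclei(records: pd.DataFrame, model: ColorModel) -> pd.DataFrame:
    """Set ``color_class`` on every record using a trained model.

    TRASH-classified records remain in the table but are excluded from
    clone calling and median normalization downstream.
    """
    out = records.copy()
    if len(out) == 0:
        out.attrs.update(records.attrs)
        return out
    if tuple(model.feature_spec) != FEATURE_SPEC:
        raise ValueError("model feature_spec does not match this package's "
                         "feature extraction order")
    feats = extract_color_features(out)
    out["color_class"] = model.predict(feats)
    out.attrs.update(records.attrs)
    return out


def classify_nuclei_rule_based(records: pd.DataFrame,
                               on_fraction: float = 0.25) -> pd.DataFrame:
    """Label-free fallback classifier on channel fractions.

    A channel is "on" when its fraction of the summed intensity exceeds
    ``on_fraction``; the on-set maps to the six color classes, while an
    empty or full on-set (no dominant color, or flat spectrum) maps to
    TRASH.
    """
    out = records.copy()
    if len(out) == 0:
        out.attrs.update(records.attrs)
        return out
    feats = extract_color_features(out)
    fracs = feats[:, 3:6]
    on = fracs > on_fraction
    names = []
    lookup = {(True, False, False): "R", (False, True, False): "G",
              (False, False, True): "B", (True, True, False): "RG",
              (True, False, True): "RB", (False, True, True): "GB"}
    for row in on:
        names.append(lookup.get(tuple(row), "TRASH"))
    out["color_class"] = names
    out.attrs.update(records.attrs)
    return out
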