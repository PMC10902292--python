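"""Mutual information and partial information decomposition (PID) of
element-feature pairs versus maze location.

Continuous features are discretized into their sample quartiles, which makes
the single-variable entropies maximal for the chosen alphabet size (four) and
renders every estimate invariant to monotone transforms of the raw feature.
Mutual information is the plug-in estimate from the joint frequency
histogram.  The PID uses the minimal-mutual-information (MMI) redundancy
ansatz: Red(f,g;L) = min[I(f;L), I(g;L)], so the less informative source has
zero unique information, and synergy follows from
Syn = I(f,g;L) - I(f;L) - I(g;L) + Red.  No small-sample bias correction is
applied; bootstrap confidence intervals quantify uncertainty instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def discretize_quartiles(values: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Quartile labels 0..3 per value (lower-closed bins, ties to the lower bin)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2 * n_bins or not np.all(np.isfinite(v)):
        raise ValueError("need at least 8 finite values")
    if np.ptp(v) == 0:
        raise ValueError("constant input has zero entropy")
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, v, side="left").astype(int)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete variables."""
    xi = pd.factorize(x)[0]
    yi = pd.factorize(y)[0]
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mutual_information_pair(f: np.ndarray, g: np.ndarray,
                            L: np.ndarray) -> tuple[float, float]:
    """I((f,g); L) in bits and normalized by H(L).

    Inputs are discrete label arrays of equal length; (f,g) is treated as one
    joint source.
    """
    f, g, L = np.asarray(f), np.asarray(g), np.asarray(L)
    if not (len(f) == len(g) == len(L)):
        raise ValueError("length mismatch")
    fg = pd.factorize(pd.Series(f).astype(str) + "|" + pd.Series(g).astype(str))[0]
    total = _mi(fg, L)
    hL = _entropy(L)
    return total, total / hL if hL > 0 else np.nan


@dataclass
class PIDResult:
    total: float
    unique_f: float
    unique_g: float
    redundancy: float
    synergy: float
    h_L: float

    @property
    def normalized(self) -> dict:
        return {k: getattr(self, k) / self.h_L
                for k in ("total", "unique_f", "unique_g", "redundancy", "synergy")}


def pid_decompose(f: np.ndarray, g: np.ndarray, L: np.ndarray) -> PIDResult:
    """MMI partial information decomposition of I((f,g);L).

    Parts are nonnegative and sum exactly to the total; the less informative
    source carries zero unique information by construction.
    """
    total, _ = mutual_information_pair(f, g, L)
    i_f = _mi(np.asarray(f), np.asarray(L))
    i_g = _mi(np.asarray(g), np.asarray(L))
    red = min(i_f, i_g)
    unique_f = i_f - red
    unique_g = i_g - red
    syn = total - i_f - i_g + red
    return PIDResult(total=total, unique_f=unique_f, unique_g=unique_g,
                     redundancy=red, synergy=max(syn, 0.0) if syn > -1e-12 else syn,
                     h_L=_entropy(np.asarray(L)))


def speed_redundancy(f: np.ndarray, speed: np.ndarray) -> float:
    """I(f;V)/H(f): fraction of a feature's variability explained by speed.

    Both inputs must already be discretized (quartile labels).
    """
    f, speed = np.asarray(f), np.asarray(speed)
    hf = _entropy(f)
    if hf == 0:
        raise ValueError("feature has zero entropy")
    return _mi(f, speed) / hf


def pid_table(table: pd.DataFrame, features: list[str],
              label_col: str = "section") -> pd.DataFrame:
    """Long-format PID over all feature pairs against the location label."""
    disc = {f: discretize_quartiles(table[f].to_numpy()) for f in features}
    L = table[label_col].to_numpy()
    rows = []
    for i, fa in enumerate(features):
        for fb in features[i + 1:]:
            r = pid_decompose(disc[fa], disc[fb], L)
            rows.append({"feature_f": fa, "feature_g": fb, "total": r.total,
                         "unique_f": r.unique_f, "unique_g": r.unique_g,
                         "redundancy": r.redundancy, "synergy": r.synergy,
                         "total_norm": r.total / r.h_L})
    return pd.DataFrame(rows)
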