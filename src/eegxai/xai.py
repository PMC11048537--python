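"""Channel-level attributions for EEG window classifiers.

Three explainers, all operating on *channel coalitions* of one window and
all implemented from the defining formulas rather than wrapped:

* :func:`exact_shapley` — the Shapley value by full coalition enumeration,
  phi_i = sum over S not containing i of |S|!(M-|S|-1)!/M! *
  [v(S u {i}) - v(S)], with the value function v(S) = f(window with the
  channels outside S masked).  Exponential in the channel count; capped at
  M <= 16.
* :func:`partition_shapley` — Owen-style values on a binary coalition tree
  (channels paired in order, padded to a power of two with empty groups):
  at every node the two children are attributed by averaging their marginal
  contributions over both join orders, recursively.  Linear-ish cost,
  exactly efficient by construction, and identical to the exact Shapley
  value for additive models.
* :func:`lime_channels` — a local ridge surrogate on random binary channel
  masks, weighted by exp(-d^2 / width^2) where d is the Euclidean distance
  of the mask vector from the unperturbed all-ones mask; the fitted
  coefficients are the per-channel importances.

Masked channels are replaced according to a :class:`MaskingPolicy`
(zeros by default — high-passed EEG is zero-mean).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .containers import ICTAL, WindowSet

__all__ = [
    "MaskingPolicy",
    "AttributionQuery",
    "CoalitionTree",
    "LimeConfig",
    "exact_shapley",
    "partition_shapley",
    "lime_channels",
    "explain_correct_ictal",
]


@dataclass
class MaskingPolicy:
    """How to replace a masked-out channel.

    ``zeros`` substitutes zeros, ``channel_mean`` the channel's own mean,
    ``reference`` the corresponding channel of a reference window.
    """

    kind: str = "zeros"
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("zeros", "channel_mean", "reference"):
            raise ValueError(f"unknown masking policy {self.kind!r}")
        if self.kind == "reference" and self.reference is None:
            raise ValueError("reference masking needs a reference window")

    def background(self, x: np.ndarray) -> np.ndarray:
        """The full replacement window for instance ``x`` (channels x L)."""
        if self.kind == "zeros":
            return np.zeros_like(x)
        if self.kind == "channel_mean":
            return np.broadcast_to(x.mean(axis=1, keepdims=True), x.shape).copy()
        ref = np.asarray(self.reference, dtype=np.float64)
        if ref.shape != x.shape:
            raise ValueError("reference window shape mismatch")
        return ref

    def apply(self, x: np.ndarray, masks: np.ndarray) -> np.ndarray:
        """Perturbed windows for binary channel masks (1 = keep).

        ``masks`` is (n_samples, n_channels); returns (n_samples, C, L).
        """
        x = np.asarray(x, dtype=np.float64)
        bg = self.background(x)
        m = np.asarray(masks, dtype=np.float64)[:, :, None]
        return m * x[None] + (1.0 - m) * bg[None]


@dataclass
class AttributionQuery:
    """One explanation request: model f, instance x, masking policy.

    The attribution target is the model's ictal-class probability.
    """

    model: object
    x: np.ndarray
    masking: MaskingPolicy = field(default_factory=MaskingPolicy)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 2:
            raise ValueError("instance must be a channels x L window")

    @property
    def n_channels(self) -> int:
        return self.x.shape[0]

    def value_function(self, batch_size: int = 256):
        """Cached v(S) = f(x with channels outside S masked), S a frozenset."""
        cache: dict[frozenset, float] = {}
        M = self.n_channels

        def v(subset) -> float:
            key = frozenset(subset)
            if key not in cache:
                mask = np.zeros((1, M))
                mask[0, sorted(key)] = 1.0
                xm = self.masking.apply(self.x, mask)
                cache[key] = float(np.atleast_1d(
                    self.model.predict_proba(xm))[0])
            return cache[key]

        return v


# ---------------------------------------------------------------------------
# exact Shapley by enumeration
# ---------------------------------------------------------------------------

def exact_shapley(query: AttributionQuery,
                  batch_size: int = 256) -> tuple[np.ndarray, float]:
    """Per-channel Shapley values by full 2^M coalition enumeration.

    Returns ``(phi, base)`` where ``base = v(empty set)``; by the
    efficiency axiom ``phi.sum() + base == f(x)``.
    """
    M = query.n_channels
    if M > 16:
        raise ValueError(
            f"exact enumeration needs 2^{M} evaluations; use partition_shapley"
        )
    masks = ((np.arange(2 ** M)[:, None] >> np.arange(M)) & 1).astype(float)
    values = np.empty(2 ** M)
    for start in range(0, 2 ** M, batch_size):
        xm = query.masking.apply(query.x, masks[start:start + batch_size])
        values[start:start + batch_size] = np.atleast_1d(
            query.model.predict_proba(xm))
    sizes = masks.sum(axis=1).astype(int)
    fact = np.array([math.factorial(k) for k in range(M + 1)], dtype=np.float64)
    phi = np.zeros(M)
    for i in range(M):
        has_i = masks[:, i] == 1
        s_without = sizes[has_i] - 1  # |S| for S = coalition minus i
        weight = fact[s_without] * fact[M - s_without - 1] / fact[M]
        idx_with = np.flatnonzero(has_i)
        idx_without = idx_with - (1 << i)
        phi[i] = np.sum(weight * (values[idx_with] - values[idx_without]))
    base = values[0]
    return phi, float(base)


def permutation_shapley(query: AttributionQuery) -> np.ndarray:
    """Independent permutation-form oracle: average marginal contribution of
    each channel over all M! join orders.  Exponential; for tests only."""
    from itertools import permutations

    M = query.n_channels
    v = query.value_function()
    phi = np.zeros(M)
    count = 0
    for order in permutations(range(M)):
        present: set[int] = set()
        for ch in order:
            before = v(present)
            present = present | {ch}
            phi[ch] += v(present) - before
        count += 1
    return phi / count


# ---------------------------------------------------------------------------
# Owen values on a binary coalition tree
# ---------------------------------------------------------------------------

@dataclass
class CoalitionTree:
    """Binary tree over channels: leaves are single channels, siblings are
    consecutive pairs, padded to the next power of two with empty groups."""

    channels: list[int]
    left: "CoalitionTree | None" = None
    right: "CoalitionTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @classmethod
    def build(cls, n_channels: int) -> "CoalitionTree":
        if n_channels < 1:
            raise ValueError("need at least one channel")
        size = 1 << max(0, (n_channels - 1).bit_length())
        slots: list[list[int]] = [[c] if c < n_channels else []
                                  for c in range(size)]

        def make(lo: int, hi: int) -> "CoalitionTree":
            if hi - lo == 1:
                return cls(channels=slots[lo])
            mid = (lo + hi) // 2
            left, right = make(lo, mid), make(mid, hi)
            return cls(channels=left.channels + right.channels,
                       left=left, right=right)

        return make(0, size)

    def validate(self, n_channels: int) -> None:
        if sorted(self.channels) != list(range(n_channels)):
            raise ValueError("tree leaves do not cover the channel set")

    def deepest_pairs(self) -> list[tuple[int, int]]:
        """Sibling pairs of real channels at the deepest level."""
        pairs = []

        def walk(node: "CoalitionTree") -> None:
            if node.is_leaf:
                return
            lc, rc = node.left, node.right
            if lc.is_leaf and rc.is_leaf and len(lc.channels) == 1 and \
                    len(rc.channels) == 1:
                pairs.append((lc.channels[0], rc.channels[0]))
            else:
                walk(lc)
                walk(rc)

        walk(self)
        return pairs


def partition_shapley(query: AttributionQuery,
                      tree: CoalitionTree | None = None,
                      pair_mean: bool = False) -> tuple[np.ndarray, float]:
    """Owen-style channel attributions on a binary coalition tree.

    At each node, the marginal contribution of the current group is split
    between its two children by averaging over both join orders, recursing
    down to single channels; contributions telescope, so
    ``phi.sum() + base == f(x)`` holds exactly.  With ``pair_mean=True``
    the two members of each deepest sibling pair both receive the mean of
    their two values (the coalition-pair convention; it preserves the sum).
    """
    M = query.n_channels
    if tree is None:
        tree = CoalitionTree.build(M)
    tree.validate(M)
    v = query.value_function()
    phi = np.zeros(M)

    def rec(node: CoalitionTree, fixed_in: frozenset, weight: float) -> None:
        if not node.channels:
            return
        if node.is_leaf:
            ch = node.channels
            phi[ch[0]] += weight * (v(fixed_in | set(ch)) - v(fixed_in))
            return
        lch, rch = set(node.left.channels), set(node.right.channels)
        rec(node.left, fixed_in, weight / 2)
        rec(node.right, frozenset(fixed_in | lch), weight / 2)
        rec(node.right, fixed_in, weight / 2)
        rec(node.left, frozenset(fixed_in | rch), weight / 2)

    rec(tree, frozenset(), 1.0)
    if pair_mean:
        for a, b in tree.deepest_pairs():
            m = 0.5 * (phi[a] + phi[b])
            phi[a] = phi[b] = m
    return phi, v(frozenset())


# ---------------------------------------------------------------------------
# LIME over channel groups
# ---------------------------------------------------------------------------

@dataclass
class LimeConfig:
    """Sampling and surrogate settings for channel-group LIME."""

    n_samples: int = 1000
    kernel_width: float | None = None  # default 0.75 * sqrt(n_channels)
    ridge_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples too small")
        if self.ridge_alpha < 0:
            raise ValueError("ridge_alpha must be non-negative")


def lime_channels(query: AttributionQuery,
                  config: LimeConfig | None = None,
                  batch_size: int = 512) -> np.ndarray:
    """Per-channel LIME coefficients for one window.

    Random binary channel masks are drawn (the first sample keeps all
    channels); masked windows are built with the query's masking policy;
    the model's ictal probability is regressed on the mask indicators with
    ridge regression, each sample weighted by exp(-d^2 / width^2) where d
    is the Euclidean distance between the mask vector and all-ones.
    """
    config = config or LimeConfig()
    M = query.n_channels
    if config.n_samples < 10 * M:
        warnings.warn(
            f"n_samples={config.n_samples} < 10 * {M} channels; "
            "coefficients may be noisy", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    masks = rng.integers(0, 2, size=(config.n_samples, M)).astype(float)
    masks[0] = 1.0
    if np.all(masks == masks[0]):
        raise ValueError("degenerate mask design: all samples identical")
    width = config.kernel_width or 0.75 * math.sqrt(M)
    d2 = np.sum((masks - 1.0) ** 2, axis=1)  # squared Euclidean distance
    weights = np.exp(-d2 / width ** 2)
    preds = np.empty(config.n_samples)
    for start in range(0, config.n_samples, batch_size):
        xm = query.masking.apply(query.x, masks[start:start + batch_size])
        preds[start:start + batch_size] = np.atleast_1d(
            query.model.predict_proba(xm))
    reg = Ridge(alpha=config.ridge_alpha, fit_intercept=True)
    reg.fit(masks, preds, sample_weight=weights)
    return np.asarray(reg.coef_, dtype=np.float64)


# ---------------------------------------------------------------------------
# dataset-level driver
# ---------------------------------------------------------------------------

def explain_correct_ictal(model, test: WindowSet,
                          methods: tuple[str, ...] = ("shap", "lime"),
                          masking: MaskingPolicy | None = None,
                          lime_config: LimeConfig | None = None,
                          pair_mean: bool = False) -> pd.DataFrame:
    """Attributions for windows labelled ictal *and* predicted ictal.

    Returns a tidy importance matrix with one signed value per
    (window, channel, method); ``shap`` uses the partition/Owen explainer.
    The window index refers to the position in ``test``.
    """
    masking = masking or MaskingPolicy()
    probs = np.atleast_1d(model.predict_proba(test.data))
    correct_ictal = np.flatnonzero((test.labels == ICTAL) & (probs >= 0.5))
    labels = test.channel_labels or [f"ch{c}" for c in range(test.n_channels)]
    rows = []
    if len(correct_ictal) == 0:
        warnings.warn("no correctly classified ictal windows", stacklevel=2)
    for w in correct_ictal:
        query = AttributionQuery(model=model, x=test.data[w], masking=masking)
        for method in methods:
            if method == "shap":
                vals, _ = partition_shapley(query, pair_mean=pair_mean)
            elif method == "lime":
                cfg = lime_config or LimeConfig()
                cfg = LimeConfig(n_samples=cfg.n_samples,
                                 kernel_width=cfg.kernel_width,
                                 ridge_alpha=cfg.ridge_alpha,
                                 seed=cfg.seed + int(w))
                vals = lime_channels(query, cfg)
            else:
                raise ValueError(f"unknown method {method!r}")
            for c in range(test.n_channels):
                rows.append((int(w), c, labels[c], method, float(vals[c])))
    return pd.DataFrame(rows, columns=["window", "channel", "channel_label",
                                       "method", "value"])
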