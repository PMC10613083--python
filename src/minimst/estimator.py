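"""scikit-learn front-end for the mini-MST outlier detector.

The detector is transductive, like :class:`~sklearn.neighbors.LocalOutlierFactor`
with ``novelty=False`` or :class:`~sklearn.cluster.DBSCAN`: it labels the
points it was fit on and does not score new data.  ``fit_predict`` follows
the scikit-learn outlier convention (-1 outlier, +1 inlier) while
``labels_`` follows the clustering convention (cluster ids, -1 for
outliers).
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array

from .core import DetectionResult, MmodConfig, detect

__all__ = ["MiniMSTOutlierDetector"]


class MiniMSTOutlierDetector(OutlierMixin, BaseEstimator):
    """Adaptive mini-minimum-spanning-tree outlier detection (MMOD).

    Builds one exact Euclidean MST, derives the termination threshold
    ``T_t`` (mean + spread of edge weights), then iteratively grows small
    Prim-style trees with threshold-scaled distances.  Points never
    absorbed into a sufficiently large tree are outliers.  No outlier
    count or contamination fraction is taken.

    Parameters
    ----------
    deviation_mode : {"std", "sum_squares"}, default="std"
        Spread term in the global threshold and the adaptive exit
        condition.
    mew1 : "first_edge" or positive float, default="first_edge"
        Initialization of a mini-tree's edge-weight record.  Use a fixed
        value (1.0 is the documented choice) for continuous
        low-dimensional data; see docs/methods.md.
    window_len : int, default=6
        Edges in the sliding stopping window, current edge included.
    least_number : int or None, default=None
        Minimum normal-cluster size in edges; ``None`` applies
        ``round(n_samples / n_features)``.
    normalize : bool, default=False
        Min-max scale each feature to [0, 1] first.
    drop_duplicates : bool, default=False
        Collapse duplicated rows; duplicates share their representative's
        label.
    root : int or "random", default=0
        Root of the global Prim MST.
    size_rule : {"ge", "gt"}, default="ge"
        Comparison of a tree's edge count against ``least_number``.
    random_state : int or None, default=None
        Seed, used only when ``root="random"``.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster id per point; -1 marks outliers.
    outlier_mask_ : ndarray of bool, shape (n_samples,)
        True where a point was flagged.
    threshold_ : float
        The run's termination threshold ``T_t``.
    least_number_ : int
        The applied minimum cluster size.
    detection_result_ : DetectionResult
        Full diagnostics including every mini-MST grown.

    Examples
    --------
    >>> from minimst import MiniMSTOutlierDetector
    >>> from minimst.synthetic import fig1_default, make_scenario
    >>> ps = make_scenario(fig1_default(seed=7))
    >>> det = MiniMSTOutlierDetector(mew1=1.0, least_number=11)
    >>> flags = det.fit_predict(ps.coordinates)   # -1 = outlier
    """

    def __init__(
        self,
        deviation_mode: str = "std",
        mew1="first_edge",
        window_len: int = 6,
        least_number: int | None = None,
        normalize: bool = False,
        drop_duplicates: bool = False,
        root=0,
        size_rule: str = "ge",
        random_state: int | None = None,
    ):
        self.deviation_mode = deviation_mode
        self.mew1 = mew1
        self.window_len = window_len
        self.least_number = least_number
        self.normalize = normalize
        self.drop_duplicates = drop_duplicates
        self.root = root
        self.size_rule = size_rule
        self.random_state = random_state

    def _config(self) -> MmodConfig:
        if isinstance(self.mew1, str):
            if self.mew1 != "first_edge":
                raise ValueError(f"mew1 must be 'first_edge' or a positive number, got {self.mew1!r}")
            policy, value = "first_edge", 1.0
        elif isinstance(self.mew1, numbers.Real):
            policy, value = "fixed", float(self.mew1)
        else:
            raise ValueError(f"mew1 must be 'first_edge' or a positive number, got {self.mew1!r}")
        return MmodConfig(
            deviation_mode=self.deviation_mode,
            mew1_policy=policy,
            mew1_value=value,
            window_len=self.window_len,
            least_number_override=self.least_number,
            normalize=self.normalize,
            drop_duplicates=self.drop_duplicates,
            root=self.root,
            size_rule=self.size_rule,
            random_state=self.random_state,
        )

    def fit(self, X, y=None):
        """Run the detection on ``X`` and store the labeling."""
        X = check_array(X, ensure_min_samples=2)
        result: DetectionResult = detect(X, self._config())
        self.n_features_in_ = X.shape[1]
        self.detection_result_ = result
        self.labels_ = result.cluster_id
        self.outlier_mask_ = result.outlier_mask
        self.threshold_ = result.t_t
        self.least_number_ = result.least_number
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return -1 for outliers, +1 for inliers."""
        self.fit(X)
        return np.where(self.outlier_mask_, -1, 1)
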