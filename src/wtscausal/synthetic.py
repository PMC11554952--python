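"""Seeded data generators and the open diabetes-progression loader.

The generators produce tables with the statistical structure the selection
and causal stages assume: linear regression data with planted relevant
features and controllable inter-feature correlation, and linear
non-Gaussian acyclic (LiNGAM) data with known coefficient matrix for
recovery studies. ``gen_wdlike`` emulates the shape of a small wearable-
device health study — 16 daily-life indicators, a near-duplicate step
pair, and a bounded wellness score target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset

DIABETES_FEATURES = ["age", "sex", "BMI", "ABP", "TC", "LDL", "HDL", "TCH", "LTG", "GLU"]
# scikit-learn / NCSU raw column names -> clinical labels
_DIABETES_COLMAP = {
    "age": "age",
    "sex": "sex",
    "bmi": "BMI",
    "bp": "ABP",
    "s1": "TC",
    "s2": "LDL",
    "s3": "HDL",
    "s4": "TCH",
    "s5": "LTG",
    "s6": "GLU",
}


@dataclass(frozen=True)
class RegressionSpec:
    """Planted-signal linear regression data.

    ``y = sum(effect_sizes[i] * X[:, relevant_indices[i]]) + N(0, noise_sd)``
    with standard-normal features sharing pairwise correlation
    ``feature_correlation`` (equicorrelated design).
    """

    n_samples: int = 200
    p_features: int = 8
    relevant_indices: tuple[int, ...] = (0,)
    effect_sizes: tuple[float, ...] = (1.0,)
    noise_sd: float = 0.5
    feature_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3 or self.p_features < 1:
            raise ValueError("need n_samples >= 3 and p_features >= 1")
        if len(self.relevant_indices) != len(self.effect_sizes):
            raise ValueError("relevant_indices and effect_sizes must align")
        if any(not 0 <= j < self.p_features for j in self.relevant_indices):
            raise ValueError("relevant_indices out of range")
        if not all(np.isfinite(self.effect_sizes)):
            raise ValueError("effect sizes must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must be in [0, 1)")


def gen_regression(spec: RegressionSpec) -> Dataset:
    """Draw a Dataset from a RegressionSpec; bitwise deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    rho = spec.feature_correlation
    Z = rng.standard_normal((spec.n_samples, spec.p_features))
    if rho > 0:
        common = rng.standard_normal((spec.n_samples, 1))
        X = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * Z
    else:
        X = Z
    signal = np.zeros(spec.n_samples)
    for j, eff in zip(spec.relevant_indices, spec.effect_sizes):
        signal += eff * X[:, j]
    y = signal + spec.noise_sd * rng.standard_normal(spec.n_samples)
    return Dataset(X=X, y=y, feature_names=[f"x{j}" for j in range(spec.p_features)])


@dataclass(frozen=True)
class LingamSpec:
    """Linear non-Gaussian acyclic model ``x = Bx + e``.

    ``b_matrix`` must be strictly lower-triangular under some permutation
    (i.e. its nonzero pattern is acyclic); ``noise`` is "uniform" or
    "laplace", both standardised to the requested scales. When ``permute``
    is true the returned columns are shuffled by a seed-derived
    permutation, so recovery studies cannot rely on column order.
    """

    b_matrix: tuple[tuple[float, ...], ...] = ((0.0, 0.0), (1.0, 0.0))
    noise: str = "uniform"
    noise_scales: tuple[float, ...] | None = None
    n_samples: int = 1000
    seed: int = 0
    permute: bool = False

    def __post_init__(self) -> None:
        B = np.asarray(self.b_matrix, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("b_matrix must be square")
        if self.noise not in ("uniform", "laplace"):
            raise ValueError("noise must be 'uniform' or 'laplace'")
        if _topological_order(B) is None:
            raise ValueError("b_matrix is cyclic; no topological order exists")


def _topological_order(B: np.ndarray) -> list[int] | None:
    """Kahn's algorithm on the nonzero pattern of B (B[i, j] != 0: j -> i)."""
    p = B.shape[0]
    indeg = [int(np.count_nonzero(B[i])) for i in range(p)]
    order = []
    queue = [i for i in range(p) if indeg[i] == 0]
    done = [False] * p
    while queue:
        j = queue.pop(0)
        order.append(j)
        done[j] = True
        for i in range(p):
            if B[i, j] != 0.0 and not done[i]:
                indeg[i] -= 1
                if indeg[i] == 0:
                    queue.append(i)
    return order if len(order) == p else None


def gen_lingam(spec: LingamSpec) -> tuple[pd.DataFrame, list[int], np.ndarray]:
    """Simulate LiNGAM data; returns (data, true causal order, true B).

    The order and B refer to the columns of the returned frame (after any
    permutation). Noise variables are zero-mean with the requested scales;
    uniform noise is ``U(-sqrt(3)s, sqrt(3)s)``, Laplace has scale
    ``s/sqrt(2)`` — both with standard deviation ``s``.
    """
    rng = np.random.default_rng(spec.seed)
    B = np.asarray(spec.b_matrix, dtype=float)
    p = B.shape[0]
    scales = (
        np.ones(p) if spec.noise_scales is None else np.asarray(spec.noise_scales, dtype=float)
    )
    if spec.noise == "uniform":
        E = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(spec.n_samples, p)) * scales
    else:
        E = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(spec.n_samples, p)) * scales
    order = _topological_order(B)
    X = np.zeros((spec.n_samples, p))
    for j in order:
        X[:, j] = X @ B[j] + E[:, j]
    if spec.permute:
        perm = rng.permutation(p)
        X = X[:, perm]
        inv = np.argsort(perm)
        order = [int(inv[j]) for j in order]
        B = B[np.ix_(perm, perm)]
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(p)])
    return df, order, B


WDLIKE_FEATURES = [
    "StressS", "RHR", "MinBO", "MaxBO", "SleepS", "DeepSC", "WUC", "BreathQ",
    "TSD", "TDSD", "TLSD", "TRSD", "ACC", "StepN", "StepD", "MHIET",
]


def gen_wdlike(seed: int = 0, n_samples: int = 150) -> Dataset:
    """A wearable-band-style health table with a wellness-score target.

    Sixteen daily indicators; StepD is a near-duplicate of StepN
    (r ~ 0.95, emulating step distance vs step count) and ACC tracks StepN
    moderately. The target loads on wake-up counts, stress, steps,
    breathing quality and sleep duration, plus noise, and is squashed onto
    a 1-10 wellness scale.
    """
    rng = np.random.default_rng(seed)
    p = len(WDLIKE_FEATURES)
    X = rng.standard_normal((n_samples, p))
    cols = {name: j for j, name in enumerate(WDLIKE_FEATURES)}
    # near-duplicate pair and a correlated activity measure
    X[:, cols["StepD"]] = X[:, cols["StepN"]] + 0.33 * rng.standard_normal(n_samples)
    X[:, cols["ACC"]] = 0.6 * X[:, cols["StepN"]] + 0.8 * rng.standard_normal(n_samples)
    # sleep durations partially compose the total
    X[:, cols["TSD"]] = (
        0.5 * X[:, cols["TDSD"]] + 0.5 * X[:, cols["TLSD"]]
        + 0.7 * rng.standard_normal(n_samples)
    )
    signal = (
        0.8 * X[:, cols["WUC"]]
        + 0.7 * X[:, cols["StressS"]]
        + 0.6 * X[:, cols["StepN"]]
        + 0.4 * X[:, cols["BreathQ"]]
        + 0.4 * X[:, cols["TSD"]]
    )
    raw = signal + 1.0 * rng.standard_normal(n_samples)
    y = 5.5 + 4.5 * np.tanh(raw / 3.0)  # 1-10 wellness scale
    return Dataset(X=X, y=y, feature_names=list(WDLIKE_FEATURES), target_name="TCMHS")


def load_diabetes(source=None) -> Dataset:
    """The 442-patient diabetes-progression table.

    ``source=None`` uses the copy bundled with scikit-learn (raw,
    unscaled); otherwise ``source`` is a path to the whitespace-delimited
    file from the NCSU variable-selection archive (columns AGE SEX BMI BP
    S1..S6 Y). Either way the columns are renamed to the clinical labels
    age, sex, BMI, ABP, TC, LDL, HDL, TCH, LTG, GLU plus Target.
    """
    if source is None:
        from sklearn.datasets import load_diabetes as _sk_load

        bunch = _sk_load(scaled=False)
        df = pd.DataFrame(bunch.data, columns=bunch.feature_names)
        df = df.rename(columns=_DIABETES_COLMAP)
        df["Target"] = bunch.target
    else:
        raw = pd.read_csv(source, sep=r"\s+")
        raw.columns = [c.strip().lower() for c in raw.columns]
        colmap = dict(_DIABETES_COLMAP)
        colmap["y"] = "Target"
        missing = [c for c in colmap if c not in raw.columns]
        if missing:
            raise ValueError(f"diabetes file is missing columns {missing}")
        df = raw.rename(columns=colmap)[DIABETES_FEATURES + ["Target"]]
    got = [c for c in df.columns if c != "Target"]
    if sorted(got) != sorted(DIABETES_FEATURES):
        raise ValueError(f"unexpected diabetes columns {got}")
    if len(df) != 442:
        raise ValueError(f"expected 442 patients, got {len(df)}")
    df = df[DIABETES_FEATURES + ["Target"]]
    return Dataset.from_dataframe(df, target="Target")
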