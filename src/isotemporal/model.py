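"""Second-order polynomial ilr regression of a health outcome on a 7-part
24-hour activity composition.

The design contains an intercept, the 6 ilr coordinates, their 6 squares, the
15 pairwise products (27 composition-derived columns in total) and 7 covariate
columns (sex indicator, age, socioeconomic z-score, 4 pubertal-status
indicators against a pre-pubertal reference): 35 columns.

Fitting is ordinary least squares (via statsmodels); only summary quantities
(coefficients, their full covariance, residual df, RSS) are retained, so a
serialized model contains no participant-level data and suffices for
prediction and substitution inference downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coda import (
    DEFAULT_SBP,
    PART_NAMES,
    CompositionError,
    SequentialBinaryPartition,
    ilr,
)

N_ILR = 6
N_POLY = 27          # 6 linear + 6 squared + 15 interactions
N_COVARIATES = 7
N_COLUMNS = 1 + N_POLY + N_COVARIATES  # 35

PUBERTAL_LEVELS = ("pre", "early", "mid", "late", "post")
SEXES = ("male", "female")

COVARIATE_COLUMNS = (
    "sex_female",
    "age",
    "ses_z",
    "puberty_early",
    "puberty_mid",
    "puberty_late",
    "puberty_post",
)

INTERACTION_PAIRS = tuple((j, k) for j in range(N_ILR) for k in range(j + 1, N_ILR))

MODEL_FORMAT = "isotemporal-model"
MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Invalid model input (missing covariates, rank deficiency, ...)."""


class ModelFormatError(ValueError):
    """A serialized model artifact failed validation."""


@dataclass(frozen=True)
class CovariateProfile:
    """Adjustment covariates for one individual.

    ``ses_z`` and ``pubertal_status`` default to the population-typical values
    (z-score 0, mid-pubertal) so a caller may supply only sex and age.
    """

    sex: str
    age: float
    ses_z: float = 0.0
    pubertal_status: str = "mid"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ModelError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.pubertal_status not in PUBERTAL_LEVELS:
            raise ModelError(
                f"pubertal_status must be one of {PUBERTAL_LEVELS}, "
                f"got {self.pubertal_status!r}"
            )
        if not np.isfinite(self.age):
            raise ModelError("missing covariate: age")
        if not np.isfinite(self.ses_z):
            raise ModelError("missing covariate: ses_z")

    def encode(self) -> np.ndarray:
        row = np.zeros(N_COVARIATES)
        row[0] = 1.0 if self.sex == "female" else 0.0
        row[1] = self.age
        row[2] = self.ses_z
        for i, level in enumerate(PUBERTAL_LEVELS[1:]):
            row[3 + i] = 1.0 if self.pubertal_status == level else 0.0
        return row


def encode_covariates(covariates: pd.DataFrame) -> np.ndarray:
    """Encode a DataFrame with columns sex, age, ses_z, pubertal_status into
    the (n, 7) covariate block (reference levels: male, pre-pubertal)."""
    for col in ("sex", "age", "ses_z", "pubertal_status"):
        if col not in covariates.columns:
            raise ModelError(f"missing covariate column: {col}")
    n = len(covariates)
    C = np.zeros((n, N_COVARIATES))
    sex = covariates["sex"].to_numpy()
    bad = ~np.isin(sex, SEXES)
    if bad.any():
        raise ModelError(f"invalid sex values: {sorted(set(sex[bad]))}")
    C[:, 0] = (sex == "female").astype(float)
    C[:, 1] = covariates["age"].to_numpy(dtype=float)
    C[:, 2] = covariates["ses_z"].to_numpy(dtype=float)
    pub = covariates["pubertal_status"].to_numpy()
    bad = ~np.isin(pub, PUBERTAL_LEVELS)
    if bad.any():
        raise ModelError(f"invalid pubertal_status values: {sorted(set(pub[bad]))}")
    for i, level in enumerate(PUBERTAL_LEVELS[1:]):
        C[:, 3 + i] = (pub == level).astype(float)
    return C


def polynomial_block(Z: np.ndarray) -> np.ndarray:
    """27 composition-derived columns: z, z^2, and z_j*z_k (j<k, lexicographic)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != N_ILR:
        raise ModelError(f"expected {N_ILR} ilr coordinates, got {Z.shape[1]}")
    inter = np.column_stack([Z[:, j] * Z[:, k] for j, k in INTERACTION_PAIRS])
    return np.column_stack([Z, Z**2, inter])


def design_column_names() -> list[str]:
    names = ["intercept"]
    names += [f"z{k + 1}" for k in range(N_ILR)]
    names += [f"z{k + 1}_sq" for k in range(N_ILR)]
    names += [f"z{j + 1}_z{k + 1}" for j, k in INTERACTION_PAIRS]
    names += list(COVARIATE_COLUMNS)
    return names


def build_design_matrix(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Full (n, 35) design: intercept | polynomial block | covariates."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != N_COVARIATES:
        raise ModelError(f"expected {N_COVARIATES} covariate columns, got {C.shape[1]}")
    if Z.shape[0] != C.shape[0]:
        raise ModelError("ilr and covariate blocks have different row counts")
    return np.column_stack([np.ones(Z.shape[0]), polynomial_block(Z), C])


def build_design_row(z: np.ndarray, cov: CovariateProfile) -> np.ndarray:
    """Single (35,) design row from ilr coordinates and a covariate profile."""
    return build_design_matrix(np.asarray(z, dtype=float)[None, :],
                               cov.encode()[None, :])[0]


@dataclass(frozen=True)
class FStatResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class FittedModel:
    """A privacy-preserving fitted model: coefficients, their covariance, and
    residual df — everything needed for prediction and contrast CIs, nothing
    participant-level."""

    outcome_name: str
    transform: str               # "identity" or "log"
    coefficients: np.ndarray     # (35,)
    covariance: np.ndarray       # (35, 35)
    residual_df: int
    sbp: SequentialBinaryPartition
    favourable: str              # "higher" or "lower" is better
    rss: float
    n_obs: int
    trim_sd: float | None = None
    column_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(design_column_names()))

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.transform not in ("identity", "log"):
            raise ModelError(f"unknown transform {self.transform!r}")
        if self.favourable not in ("higher", "lower"):
            raise ModelError("favourable must be 'higher' or 'lower'")
        if self.coefficients.shape != (N_COLUMNS,):
            raise ModelError(f"coefficients must have length {N_COLUMNS}")
        if self.covariance.shape != (N_COLUMNS, N_COLUMNS):
            raise ModelError(f"covariance must be {N_COLUMNS}x{N_COLUMNS}")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ModelError("coefficient covariance is not symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-8:
            raise ModelError("coefficient covariance is not positive semi-definite")
        if self.residual_df != self.n_obs - N_COLUMNS:
            raise ModelError("residual_df must equal n_obs - 35")

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


FAVOURABLE_DEFAULTS = {
    "bodyfat": "lower",
    "psychosocial": "higher",
    "academic": "higher",
}


def _prepare_xy(compositions, covariates, outcome, transform,
                sbp: SequentialBinaryPartition):
    if isinstance(covariates, pd.DataFrame):
        C = encode_covariates(covariates)
    else:
        C = np.asarray(covariates, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if isinstance(compositions, pd.DataFrame):
        V = compositions[list(PART_NAMES)].to_numpy(dtype=float)
    else:
        V = np.asarray(compositions, dtype=float)
    if not (len(V) == len(C) == len(y)):
        raise ModelError("compositions, covariates and outcome differ in length")
    # complete cases only
    keep = np.isfinite(y) & np.isfinite(C).all(axis=1)
    V, C, y = V[keep], C[keep], y[keep]
    if np.any(V <= 0):
        raise CompositionError(
            "compositions must be strictly positive before fitting; apply "
            "zero replacement first"
        )
    if transform == "log":
        if np.any(y <= 0):
            raise ModelError("log transform requires strictly positive outcomes")
        y = np.log(y)
    elif transform != "identity":
        raise ModelError(f"unknown transform {transform!r}")
    Z = ilr(V, sbp)
    X = build_design_matrix(Z, C)
    return X, y


def fit_outcome_model(compositions, covariates, outcome, outcome_name: str,
                      transform: str = "identity",
                      sbp: SequentialBinaryPartition = DEFAULT_SBP,
                      favourable: str | None = None,
                      trim_sd: float | None = None) -> FittedModel:
    """Ordinary-least-squares fit of one outcome on the 35-column design.

    Rows with a missing outcome or covariate are dropped (complete-case
    analysis). Raises on a rank-deficient design rather than silently using a
    pseudo-inverse.
    """
    X, y = _prepare_xy(compositions, covariates, outcome, transform, sbp)
    n = len(y)
    if n <= N_COLUMNS:
        raise ModelError(f"need more than {N_COLUMNS} complete cases, have {n}")
    if np.linalg.matrix_rank(X) < N_COLUMNS:
        raise ModelError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    if favourable is None:
        favourable = FAVOURABLE_DEFAULTS.get(outcome_name, "higher")
    return FittedModel(
        outcome_name=outcome_name,
        transform=transform,
        coefficients=res.params,
        covariance=res.cov_params(),
        residual_df=int(res.df_resid),
        sbp=sbp,
        favourable=favourable,
        rss=float(res.ssr),
        n_obs=n,
        trim_sd=trim_sd,
    )


def compositional_f_test(full: FittedModel, compositions, covariates,
                         outcome) -> FStatResult:
    """Partial F-test of the 27 composition-derived columns against the
    covariate-only model, on the same complete cases as ``full``."""
    X, y = _prepare_xy(compositions, covariates, outcome, full.transform, full.sbp)
    if len(y) != full.n_obs:
        raise ModelError(
            f"data has {len(y)} complete cases but the model was fit on "
            f"{full.n_obs}; the reduced fit must use the same rows"
        )
    X_red = np.column_stack([X[:, 0], X[:, 1 + N_POLY:]])  # intercept + covariates
    rss_red = float(sm.OLS(y, X_red).fit().ssr)
    df2 = full.residual_df
    F = ((rss_red - full.rss) / N_POLY) / (full.rss / df2)
    return FStatResult(F=float(F), df1=N_POLY, df2=df2,
                       p=float(stats.f.sf(F, N_POLY, df2)))


def aic(model: FittedModel) -> float:
    """Akaike information criterion, Gaussian OLS convention
    AIC = n*ln(RSS/n) + 2k with k = 35 mean parameters + 1 variance parameter
    (the additive constant n*(ln 2pi + 1) is dropped; only differences between
    models fit to the same data are meaningful)."""
    n = model.n_obs
    k = N_COLUMNS + 1
    return n * np.log(model.rss / n) + 2 * k


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "format", "version", "outcome_name", "transform", "favourable",
    "coefficients", "covariance", "residual_df", "n_obs", "rss", "trim_sd",
    "sbp_matrix", "parts", "column_names",
}


def serialize_model(model: FittedModel, path) -> None:
    """Write the model to versioned JSON. The artifact holds only summary
    statistics — never unit-level records."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "outcome_name": model.outcome_name,
        "transform": model.transform,
        "favourable": model.favourable,
        "coefficients": model.coefficients.tolist(),
        "covariance": model.covariance.tolist(),
        "residual_df": model.residual_df,
        "n_obs": model.n_obs,
        "rss": model.rss,
        "trim_sd": model.trim_sd,
        "sbp_matrix": model.sbp.matrix.tolist(),
        "parts": list(model.sbp.parts),
        "column_names": list(model.column_names),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path) -> FittedModel:
    """Load and validate a serialized model. Rejects unknown keys (in
    particular any record-level arrays), format/version mismatches, and
    malformed covariance matrices."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"not valid JSON: {e}") from e
    if not isinstance(payload, dict):
        raise ModelFormatError("model file must contain a JSON object")
    if payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError("not an isotemporal model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {payload.get('version')!r}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    unknown = set(payload) - _ALLOWED_KEYS
    if unknown:
        raise ModelFormatError(
            f"unexpected keys in model file (unit-level data is forbidden): "
            f"{sorted(unknown)}"
        )
    missing = _ALLOWED_KEYS - set(payload)
    if missing:
        raise ModelFormatError(f"missing keys in model file: {sorted(missing)}")
    if tuple(payload["parts"]) != PART_NAMES:
        raise ModelFormatError(f"unexpected part order: {payload['parts']}")
    sbp = SequentialBinaryPartition(np.array(payload["sbp_matrix"]),
                                    tuple(payload["parts"]))
    try:
        model = FittedModel(
            outcome_name=payload["outcome_name"],
            transform=payload["transform"],
            coefficients=np.array(payload["coefficients"], dtype=float),
            covariance=np.array(payload["covariance"], dtype=float),
            residual_df=int(payload["residual_df"]),
            sbp=sbp,
            favourable=payload["favourable"],
            rss=float(payload["rss"]),
            n_obs=int(payload["n_obs"]),
            trim_sd=payload["trim_sd"],
            column_names=tuple(payload["column_names"]),
        )
    except ModelError as e:
        raise ModelFormatError(str(e)) from e
    return model
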