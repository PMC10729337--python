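"""Development-cohort container, CSV I/O, and synthetic cohort generation.

A :class:`Cohort` is the rectangular development dataset a clinical
prediction model is built from: one binary outcome (1 = event, e.g. 30-day
death after myocardial infarction) and a matrix of named numeric predictors.
Missing values are rejected at load time — the bootstrap instability
procedure presumes a complete development dataset, and silent imputation
would hide part of the model-development uncertainty it is meant to expose.

The synthetic generator emulates a GUSTO-I-like cohort: eight candidate
predictors (sex, age, hypertension, hypotension, tachycardia, previous MI,
ST elevation, systolic blood pressure) and a binary 30-day mortality outcome
at roughly 7% prevalence drawn from a known logistic model, so that tests
can compare estimates against the generating truth.
"""

from __future__ import annotations

import json
import logging
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

BINARY = "binary"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class Cohort:
    """A complete development dataset: ids, binary outcome, predictor matrix.

    Parameters
    ----------
    ids : ndarray
        Unique row identifiers, length ``n``.
    outcome : ndarray
        Binary event indicator (0/1), length ``n``; 1 marks an event.
    predictors : ndarray
        ``n x p`` float matrix, no missing values.
    predictor_names : tuple of str
        One label per predictor column.
    predictor_kinds : tuple of str
        Per-predictor flag, ``"binary"`` or ``"continuous"``.
    truth : dict, optional
        For synthetic cohorts: the generating intercept, coefficients and
        per-row true event probabilities, retained for truth-known testing.
    """

    ids: np.ndarray
    outcome: np.ndarray
    predictors: np.ndarray
    predictor_names: tuple[str, ...]
    predictor_kinds: tuple[str, ...]
    truth: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "ids", np.asarray(self.ids))
        object.__setattr__(self, "outcome", np.asarray(self.outcome))
        object.__setattr__(
            self, "predictors", np.asarray(self.predictors, dtype=float)
        )
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        object.__setattr__(self, "predictor_kinds", tuple(self.predictor_kinds))
        self._validate()

    def _validate(self) -> None:
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            raise ValidationError("row ids must be unique")
        if self.outcome.shape != (n,):
            raise ValidationError("outcome length must match ids")
        if not np.isin(self.outcome, (0, 1)).all():
            bad = np.unique(self.outcome[~np.isin(self.outcome, (0, 1))])
            raise ValidationError(
                f"outcome must be coded 0/1; found values {bad.tolist()}"
            )
        if self.predictors.ndim != 2 or self.predictors.shape[0] != n:
            raise ValidationError("predictors must be an n x p matrix")
        p = self.predictors.shape[1]
        if len(self.predictor_names) != p:
            raise ValidationError("one name per predictor column required")
        if len(self.predictor_kinds) != p:
            raise ValidationError("one kind flag per predictor column required")
        if any(k not in (BINARY, CONTINUOUS) for k in self.predictor_kinds):
            raise ValidationError("predictor kinds must be 'binary' or 'continuous'")
        if not np.isfinite(self.predictors).all():
            rows = np.where(~np.isfinite(self.predictors).all(axis=1))[0]
            raise ValidationError(
                f"missing or non-finite predictor values in rows {rows.tolist()[:20]}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def prevalence(self) -> float:
        return self.n_events / self.n

    @property
    def has_both_classes(self) -> bool:
        return 0 < self.n_events < self.n

    def predictor(self, name: str) -> np.ndarray:
        try:
            j = self.predictor_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"unknown predictor {name!r}; available: {list(self.predictor_names)}"
            ) from None
        return self.predictors[:, j]

    def take(self, indices: np.ndarray, new_ids: bool = False) -> "Cohort":
        """Row-subset (or resample) the cohort.

        With ``new_ids=True`` rows are relabelled 0..m-1, which permits
        duplicate source rows (bootstrap resampling).
        """
        indices = np.asarray(indices)
        ids = np.arange(len(indices)) if new_ids else self.ids[indices]
        truth = None
        if self.truth is not None:
            truth = dict(self.truth)
            if "true_probabilities" in truth:
                truth["true_probabilities"] = np.asarray(
                    truth["true_probabilities"]
                )[indices]
        return Cohort(
            ids=ids,
            outcome=self.outcome[indices],
            predictors=self.predictors[indices],
            predictor_names=self.predictor_names,
            predictor_kinds=self.predictor_kinds,
            truth=truth,
        )

    def to_dataframe(self, outcome_name: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(self.predictors, columns=list(self.predictor_names))
        df.insert(0, outcome_name, self.outcome)
        df.insert(0, "id", self.ids)
        return df


def _infer_kinds(X: np.ndarray) -> tuple[str, ...]:
    # <=2 distinct values -> binary
    return tuple(
        BINARY if len(np.unique(X[:, j])) <= 2 else CONTINUOUS
        for j in range(X.shape[1])
    )


def load_cohort(
    path: str | Path,
    outcome_name: str,
    predictor_names: Sequence[str] | None = None,
) -> Cohort:
    """Read a cohort from a headed CSV file.

    ``predictor_names`` defaults to every non-outcome, non-``id`` column.
    Binary/continuous kinds are inferred (at most two distinct values means
    binary). Missing cells are a hard error naming the offending rows; the
    instability procedure requires a complete development dataset.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if outcome_name not in df.columns:
        raise ConfigurationError(
            f"outcome column {outcome_name!r} not in {list(df.columns)}"
        )
    if predictor_names is None:
        predictor_names = [
            c for c in df.columns if c not in (outcome_name, "id")
        ]
    missing_cols = [c for c in predictor_names if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"predictor columns {missing_cols} not in {list(df.columns)}"
        )
    sub = df[list(predictor_names) + [outcome_name]]
    if sub.isna().any().any():
        rows = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValidationError(
            f"missing values in rows {rows[:20]} (no silent imputation; "
            "complete data are required)"
        )
    outcome = df[outcome_name].to_numpy()
    if not np.isin(outcome, (0, 1)).all():
        bad = sorted(set(outcome) - {0, 1})
        raise ValidationError(f"outcome {outcome_name!r} must be 0/1; found {bad}")
    X = df[list(predictor_names)].to_numpy(dtype=float)
    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
    return Cohort(
        ids=ids,
        outcome=outcome.astype(np.int64),
        predictors=X,
        predictor_names=tuple(predictor_names),
        predictor_kinds=_infer_kinds(X),
    )


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    outcome_name: str = "outcome",
    metadata: dict | None = None,
) -> None:
    """Write a cohort as CSV plus a sidecar ``.meta.json`` provenance file."""
    path = Path(path)
    cohort.to_dataframe(outcome_name).to_csv(path, index=False)
    meta = {
        "outcome": outcome_name,
        "predictors": list(cohort.predictor_names),
        "predictor_kinds": list(cohort.predictor_kinds),
        "n": cohort.n,
        "n_events": cohort.n_events,
    }
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bernoulli:
    """Binary predictor generator: draws Bernoulli(q)."""

    q: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if not 0 < self.q < 1:
            raise ValidationError(f"Bernoulli rate must be in (0,1); got {self.q}")
        return rng.binomial(1, self.q, n).astype(float)

    kind = BINARY


@dataclass(frozen=True)
class Normal:
    """Continuous predictor generator: Normal(mu, sigma), optionally
    standardized at generation so its coefficient is on the per-SD scale."""

    mu: float = 0.0
    sigma: float = 1.0
    standardize: bool = True

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma <= 0:
            raise ValidationError(
                f"continuous predictor requires sigma > 0; got {self.sigma}"
            )
        x = rng.normal(self.mu, self.sigma, n)
        if self.standardize:
            x = (x - self.mu) / self.sigma
        return x

    kind = CONTINUOUS


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating truth for a synthetic development cohort.

    ``true_intercept`` and ``true_coefficients`` are on the log-odds scale;
    the outcome is drawn Bernoulli(expit(intercept + X beta)).
    """

    n: int
    true_intercept: float
    true_coefficients: tuple[float, ...]
    predictor_names: tuple[str, ...]
    predictor_generators: tuple[Bernoulli | Normal, ...]
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("n must be at least 2")
        k = len(self.predictor_names)
        if not (len(self.true_coefficients) == len(self.predictor_generators) == k):
            raise ValidationError(
                "coefficients, names and generators must have equal length"
            )

    def with_(self, **kwargs) -> "SyntheticCohortSpec":
        return replace(self, **kwargs)


# Default GUSTO-like spec. Marginal predictor frequencies approximate an
# acute-MI trial population; coefficients are plausible log-odds effects for
# 30-day mortality. The intercept was calibrated once by Monte-Carlo search
# (n = 4e5) so the implied marginal prevalence is 0.070 and the true-model
# c-statistic is ~0.80, then frozen.
GUSTO_LIKE_NAMES = (
    "sex",
    "age",
    "hypertension",
    "hypotension",
    "tachycardia",
    "previous_mi",
    "st_elevation",
    "sysbp",
)
GUSTO_LIKE_COEFFICIENTS = (0.35, 1.00, 0.10, 0.80, 0.45, 0.40, 0.30, -0.60)
GUSTO_LIKE_INTERCEPT = -3.70
GUSTO_LIKE_GENERATORS = (
    Bernoulli(0.25),          # sex: 1 = female
    Normal(62.0, 12.0),       # age, standardized (coefficient per SD)
    Bernoulli(0.38),          # history of hypertension
    Bernoulli(0.08),          # hypotension at presentation
    Bernoulli(0.32),          # tachycardia (pulse > 80)
    Bernoulli(0.17),          # previous myocardial infarction
    Bernoulli(0.37),          # ST elevation on ECG
    Normal(129.0, 20.0),      # systolic blood pressure, standardized
)


def gusto_like_spec(n: int = 40_000, seed: int = 0) -> SyntheticCohortSpec:
    """Default synthetic spec: 8 predictors, ~7% 30-day mortality."""
    return SyntheticCohortSpec(
        n=n,
        true_intercept=GUSTO_LIKE_INTERCEPT,
        true_coefficients=GUSTO_LIKE_COEFFICIENTS,
        predictor_names=GUSTO_LIKE_NAMES,
        predictor_generators=GUSTO_LIKE_GENERATORS,
        seed=seed,
    )


def generate_synthetic_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Draw a cohort from the spec's generating logistic model.

    Deterministic given ``spec.seed``. The generating intercept,
    coefficients and per-row true probabilities are retained in
    ``cohort.truth`` for truth-known testing.
    """
    rng = np.random.default_rng(spec.seed)
    X = np.column_stack(
        [g.draw(rng, spec.n) for g in spec.predictor_generators]
    )
    beta = np.asarray(spec.true_coefficients, dtype=float)
    true_p = expit(spec.true_intercept + X @ beta)
    outcome = rng.binomial(1, true_p).astype(np.int64)
    return Cohort(
        ids=np.arange(spec.n),
        outcome=outcome,
        predictors=X,
        predictor_names=spec.predictor_names,
        predictor_kinds=tuple(g.kind for g in spec.predictor_generators),
        truth={
            "true_intercept": spec.true_intercept,
            "true_coefficients": beta,
            "true_probabilities": true_p,
            "seed": spec.seed,
        },
    )


def subsample_cohort(
    cohort: Cohort,
    m: int,
    seed: int,
    exact_events: int | None = None,
    max_redraws: int = 100,
) -> Cohort:
    """Simple random sample of ``m`` rows without replacement.

    Redraws (with a logged count) until both outcome classes are present,
    since a single-class sample cannot support model development. With
    ``exact_events`` the sample is instead drawn conditional on exactly that
    number of events.
    """
    if not 2 <= m <= cohort.n:
        raise ValidationError(f"m must be in [2, {cohort.n}]; got {m}")
    rng = np.random.default_rng(seed)
    if exact_events is not None:
        if not 1 <= exact_events < m:
            raise ValidationError("exact_events must be in [1, m)")
        ev = np.where(cohort.outcome == 1)[0]
        nev = np.where(cohort.outcome == 0)[0]
        if exact_events > len(ev) or m - exact_events > len(nev):
            raise ValidationError("not enough rows in one outcome class")
        idx = np.concatenate(
            [
                rng.choice(ev, exact_events, replace=False),
                rng.choice(nev, m - exact_events, replace=False),
            ]
        )
        idx = rng.permutation(idx)
        return cohort.take(idx)
    redraws = 0
    while True:
        idx = rng.choice(cohort.n, m, replace=False)
        sub = cohort.take(idx)
        if sub.has_both_classes:
            if redraws:
                logger.info("subsample_cohort: %d redraw(s) for class balance", redraws)
            return sub
        redraws += 1
        if redraws > max_redraws:
            raise ValidationError(
                "could not draw a subsample containing both outcome classes"
            )


# ---------------------------------------------------------------------------
# Optional real-data fetcher (network; never required by the test suite)
# ---------------------------------------------------------------------------

GUSTO_URL = "https://hbiostat.org/data/gusto.rda"

# Source-column mapping for the public GUSTO-I table. The flags for
# hypertension/hypotension/tachycardia are not printed anywhere
# authoritative, so the mapping is data-driven, recorded in the sidecar
# metadata, and overridable — treat real-data numbers as a reproduction
# with this caveat.
GUSTO_COLUMN_MAP = {
    "outcome": "day30",
    "sex": "sex",            # female = 1
    "age": "age",
    "hypertension": "htn",
    "hypotension": "hyp",
    "tachycardia": "hrt",
    "previous_mi": "pmi",
    "st_elevation": "ste",
    "sysbp": "sysbp",
}

_R_FETCH = """
con <- url("{url}")
load(con); close(con)
obj <- get(ls()[1])
write.csv(obj, "{csv}", row.names = FALSE)
"""


def fetch_gusto(
    cache_dir: str | Path,
    column_map: dict | None = None,
    url: str = GUSTO_URL,
) -> Cohort:
    """Download (or reuse a cached copy of) the GUSTO-I trial table.

    Requires network on the first call and an ``Rscript`` binary to decode
    the .rda serialization; afterwards the raw CSV cache is reused offline.
    Returns a cohort with the 30-day death outcome and the eight standard
    candidate predictors; the column mapping used is written to the cache
    metadata.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    raw_csv = cache_dir / "gusto_raw.csv"
    cmap = dict(GUSTO_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if not raw_csv.exists():
        script = _R_FETCH.format(url=url, csv=raw_csv)
        try:
            subprocess.run(
                ["Rscript", "-e", script], check=True, capture_output=True, text=True
            )
        except (subprocess.CalledProcessError, FileNotFoundError) as e:
            detail = getattr(e, "stderr", "") or str(e)
            raise IOError(
                f"could not fetch GUSTO-I from {url} (retry with network, or "
                f"place a CSV at {raw_csv}): {detail}"
            ) from e
    df = pd.read_csv(raw_csv)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(
            f"GUSTO columns {missing} not found; available: {list(df.columns)}. "
            "Pass column_map to override."
        )
    out = pd.DataFrame({"id": np.arange(len(df))})
    for target, source in cmap.items():
        col = df[source]
        if col.dtype == object or str(col.dtype) == "category":
            # factor columns: event/positive level -> 1
            col = (
                col.astype(str)
                .str.lower()
                .isin(("yes", "dead", "death", "female", "1", "true"))
                .astype(int)
            )
        out[target if target != "outcome" else "day30"] = col.to_numpy()
    mapped_csv = cache_dir / "gusto_cohort.csv"
    out.to_csv(mapped_csv, index=False)
    (cache_dir / "gusto_cohort.meta.json").write_text(
        json.dumps({"url": url, "column_map": cmap}, indent=2)
    )
    return load_cohort(
        mapped_csv,
        outcome_name="day30",
        predictor_names=[k for k in cmap if k != "outcome"],
    )
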