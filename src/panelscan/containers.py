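"""Shared in-memory containers and error types.

All tabular data are pandas objects; :class:`OmicsMatrix` is a thin wrapper
that tags a genes-or-drugs x samples matrix with its measurement role and
per-column metadata so downstream stages can validate their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("expression", "cnv", "ic50", "essentiality")


class PanelscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PanelscanError):
    """A simulation or pipeline configuration value is invalid."""


class InputError(PanelscanError):
    """An input table violates the documented contract."""


@dataclass
class OmicsMatrix:
    """A numeric feature x sample matrix with a role tag.

    Parameters
    ----------
    values
        DataFrame with unique row ids (genes or drugs) and unique column ids
        (samples or cell lines). Expression values are FPKM (nonnegative),
        CNV values are GISTIC-thresholded integers in {-2,-1,0,1,2}, IC50
        values are on natural-log scale and may contain NaN.
    role
        One of ``expression``, ``cnv``, ``ic50``, ``essentiality``.
    col_meta
        Optional per-sample metadata indexed by column id. Expression
        cohorts carry ``cancer_type``, ``is_tumor`` and ``tissue`` columns.
    log_transformed
        Whether expression values have already been log-transformed; the
        flag exists so the transform is applied exactly once.
    """

    values: pd.DataFrame
    role: str
    col_meta: pd.DataFrame | None = None
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.values.index.has_duplicates:
            raise InputError("duplicate row ids in OmicsMatrix")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate column ids in OmicsMatrix")
        if self.role == "cnv":
            vals = self.values.to_numpy()
            if not np.isin(vals[~np.isnan(vals)], [-2, -1, 0, 1, 2]).all():
                raise InputError("cnv matrix entries must be in {-2,-1,0,1,2}")
        if self.role == "expression" and not self.log_transformed:
            if (self.values.to_numpy() < 0).any():
                raise InputError("FPKM expression must be nonnegative")
        if self.col_meta is not None:
            missing = self.values.columns.difference(self.col_meta.index)
            if len(missing):
                raise InputError(f"col_meta missing entries for {len(missing)} columns")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def meta(self, column: str) -> pd.Series:
        if self.col_meta is None or column not in self.col_meta.columns:
            raise InputError(f"column metadata {column!r} not available")
        return self.col_meta.loc[self.values.columns, column]

    def log2(self, pseudocount: float = 1.0) -> "OmicsMatrix":
        """Return a log2(x + pseudocount) copy; no-op guard against double transforms."""
        if self.log_transformed:
            return self
        return OmicsMatrix(
            values=np.log2(self.values + pseudocount),
            role=self.role,
            col_meta=self.col_meta,
            log_transformed=True,
        )


@dataclass
class SurvivalFit:
    """A univariate survival association for one gene (or grouping label)."""

    label: str
    hr: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    logrank_chi2: float = np.nan
    p_value: float = np.nan
    cutpoint: float | None = None
    classification: str = "ns"  # risky | protective | ns
    skipped: str | None = None  # reason string when the gene was not analyzed
    converged: bool = True
    selection_biased_p: bool = False

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "logrank_chi2": self.logrank_chi2,
            "p_value": self.p_value,
            "cutpoint": np.nan if self.cutpoint is None else self.cutpoint,
            "classification": self.classification,
            "skipped": "" if self.skipped is None else self.skipped,
            "converged": self.converged,
        }


@dataclass
class Manifest:
    """Planted ground truth of a simulation, for recovery tests and reports."""

    entries: dict = field(default_factory=dict)

    def record(self, key: str, value) -> None:
        self.entries[key] = value

    def to_text(self) -> str:
        lines = []
        for key in sorted(self.entries):
            lines.append(f"{key}: {self.entries[key]}")
        return "\n".join(lines) + "\n"
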