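"""Item-response data container and delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ItemResponseMatrix"]

#: covariate columns recognised in delimited-text matrices
_COVARIATE_COLS = ("age", "gender", "education")


@dataclass
class ItemResponseMatrix:
    """Respondent x item ordinal responses with group labels.

    Parameters
    ----------
    responses
        Float array of shape (n_respondents, n_items); missing entries are NaN.
        Non-missing values must be integers in ``[min_category, min_category +
        n_categories - 1]``.
    item_names
        Column identifiers, e.g. ``item01`` .. ``item12``.
    group
        Group label per respondent (e.g. ``population`` / ``clinical``).
    covariates
        Optional per-respondent covariates (age, gender, education).
    """

    responses: np.ndarray
    item_names: list[str]
    group: np.ndarray
    covariates: pd.DataFrame | None = None
    n_categories: int = 7
    min_category: int = 1
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D array")
        n, k = self.responses.shape
        if n < 1:
            raise ValueError("need at least one respondent")
        if k < 2:
            raise ValueError("need at least two items")
        if len(self.item_names) != k:
            raise ValueError("item_names length does not match responses")
        if len(self.group) != n:
            raise ValueError("group length does not match responses")
        obs = self.responses[~np.isnan(self.responses)]
        lo, hi = self.min_category, self.min_category + self.n_categories - 1
        if obs.size and (np.any(obs < lo) or np.any(obs > hi) or np.any(obs != np.round(obs))):
            raise ValueError(
                f"non-missing responses must be integers in [{lo}, {hi}]"
            )
        self._validated = True

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(str(g), None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "ItemResponseMatrix":
        """Row-subset by boolean mask; covariates follow along."""
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[mask].reset_index(drop=True)
        return ItemResponseMatrix(
            responses=self.responses[mask].copy(),
            item_names=list(self.item_names),
            group=self.group[mask].copy(),
            covariates=cov,
            n_categories=self.n_categories,
            min_category=self.min_category,
        )

    def for_group(self, label: str) -> "ItemResponseMatrix":
        return self.subset(np.asarray([str(g) == label for g in self.group]))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_names)
        df["group"] = [str(g) for g in self.group]
        if self.covariates is not None:
            for c in self.covariates.columns:
                df[c] = self.covariates[c].to_numpy()
        return df

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        # responses are small integers; write them without trailing ".0"
        for c in self.item_names:
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_categories: int = 7, min_category: int = 1
    ) -> "ItemResponseMatrix":
        if "group" not in df.columns:
            raise ValueError("matrix must have a 'group' column")
        item_cols = [
            c for c in df.columns if c != "group" and c not in _COVARIATE_COLS
        ]
        cov_cols = [c for c in df.columns if c in _COVARIATE_COLS]
        cov = df[cov_cols].reset_index(drop=True) if cov_cols else None
        return cls(
            responses=df[item_cols].to_numpy(dtype=float),
            item_names=item_cols,
            group=df["group"].to_numpy(),
            covariates=cov,
            n_categories=n_categories,
            min_category=min_category,
        )

    @classmethod
    def from_csv(cls, path, n_categories: int = 7, min_category: int = 1) -> "ItemResponseMatrix":
        return cls.from_dataframe(
            pd.read_csv(path), n_categories=n_categories, min_category=min_category
        )
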