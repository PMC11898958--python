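"""Core domain types for biomimetic-chromatography QSRR analysis.

The package models a small-molecule dataset characterised on three
biomimetic HPLC systems: a C18 reversed phase (lipophilicity, CHI_C18),
an immobilised-artificial-membrane phase (phospholipid affinity,
CHI_IAM) and a human-serum-albumin phase (plasma-protein binding,
LogK_HSA / %HSA).  Molecular descriptors enter as plain numeric tables
computed by external software; models are ordinary least-squares fits
over small descriptor subsets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "RetentionTable",
    "DescriptorMatrix",
    "QSRRModel",
    "GAConfig",
    "AnalysisConfig",
    "ENDPOINT_COLUMNS",
]

#: the four measured endpoint columns, in table order
ENDPOINT_COLUMNS = ("chi_c18", "chi_iam", "logk_hsa", "pct_hsa")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with its measured chromatographic indices.

    Parameters
    ----------
    id : int
        Positive row number within the source table.
    name : str
        Compound name, unique within a table.
    chi_c18 : float
        Chromatographic hydrophobicity index on the C18 phase
        (dimensionless, roughly 0-110).
    chi_iam : float
        Chromatographic hydrophobicity index on the IAM phase.
    logk_hsa : float
        log10 affinity derived from retention on the HSA column.
    pct_hsa : float
        Percent bound to human serum albumin, in (0, 100).
    smiles : str, optional
        Structure string, bookkeeping only.
    """

    id: int
    name: str
    chi_c18: float
    chi_iam: float
    logk_hsa: float
    pct_hsa: float
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"compound id must be positive, got {self.id}")
        if not (0.0 < self.pct_hsa < 100.0):
            raise ValueError(
                f"pct_hsa must lie in (0, 100), got {self.pct_hsa} for {self.name!r}"
            )


class RetentionTable:
    """Ordered collection of :class:`CompoundRecord` with unique names."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self.records: tuple[CompoundRecord, ...] = tuple(records)
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def column(self, name: str) -> np.ndarray:
        """Extract one endpoint column in record order."""
        if name not in ENDPOINT_COLUMNS:
            raise KeyError(f"unknown endpoint column {name!r}; choose from {ENDPOINT_COLUMNS}")
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        return df.set_index("id")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RetentionTable):
            return NotImplemented
        return self.records == other.records


class DescriptorMatrix:
    """Compound x descriptor numeric table with provenance notes.

    Thin wrapper over a float DataFrame (rows = compounds) that enforces
    completeness and carries per-descriptor provenance (software/block).
    """

    def __init__(
        self,
        values: pd.DataFrame | np.ndarray,
        compound_names: Sequence[str] | None = None,
        descriptor_names: Sequence[str] | None = None,
        provenance: Mapping[str, str] | None = None,
    ):
        if isinstance(values, pd.DataFrame):
            df = values.astype(float)
            if compound_names is not None:
                df.index = list(compound_names)
            if descriptor_names is not None:
                df.columns = list(descriptor_names)
        else:
            arr = np.asarray(values, dtype=float)
            if compound_names is None or descriptor_names is None:
                raise ValueError("array input requires compound_names and descriptor_names")
            df = pd.DataFrame(arr, index=list(compound_names), columns=list(descriptor_names))
        if df.isna().any().any():
            bad = [(str(i), str(c)) for i, c in zip(*np.where(df.isna().to_numpy()))]
            raise ValueError(f"descriptor matrix contains missing values at {bad[:5]} ...")
        if df.index.duplicated().any():
            raise ValueError(
                f"duplicate compound names: {sorted(df.index[df.index.duplicated()].unique())}"
            )
        if df.columns.duplicated().any():
            raise ValueError(
                f"duplicate descriptor names: {sorted(df.columns[df.columns.duplicated()].unique())}"
            )
        self.frame = df
        self.provenance: dict[str, str] = dict(provenance or {})

    @property
    def compound_names(self) -> list[str]:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset(self, descriptors: Sequence[str]) -> "DescriptorMatrix":
        missing = [d for d in descriptors if d not in self.frame.columns]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        return DescriptorMatrix(
            self.frame[list(descriptors)],
            provenance={d: self.provenance[d] for d in descriptors if d in self.provenance},
        )


@dataclass
class QSRRModel:
    """A fitted (or reference) linear retention model.

    ``predict`` for a descriptor vector x is
    ``intercept + sum_j coefficients[j] * x[j]``.
    """

    endpoint_name: str
    intercept: float
    coefficients: dict[str, float]
    training_ids: list | None = None
    fit_meta: dict = field(default_factory=dict)
    fitted_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("coefficient map must be non-empty")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def predict_one(self, x: Mapping[str, float]) -> float:
        missing = [d for d in self.coefficients if d not in x]
        if missing:
            raise KeyError(f"descriptor vector missing {missing}")
        return self.intercept + sum(c * float(x[d]) for d, c in self.coefficients.items())

    def predict(self, X) -> np.ndarray:
        """Predict for a DescriptorMatrix, DataFrame, mapping or 2-D array.

        Array input must supply columns in ``descriptor_names`` order.
        """
        if isinstance(X, Mapping):
            return np.array([self.predict_one(X)])
        if isinstance(X, DescriptorMatrix):
            X = X.frame
        if isinstance(X, pd.DataFrame):
            missing = [d for d in self.coefficients if d not in X.columns]
            if missing:
                raise KeyError(f"descriptor matrix missing {missing}")
            M = X[self.descriptor_names].to_numpy(dtype=float)
        else:
            M = np.atleast_2d(np.asarray(X, dtype=float))
            if M.shape[1] != len(self.coefficients):
                raise ValueError(
                    f"expected {len(self.coefficients)} descriptor columns, got {M.shape[1]}"
                )
        beta = np.array([self.coefficients[d] for d in self.descriptor_names])
        return self.intercept + M @ beta


@dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor-subset selection.

    Defaults follow the study conditions: a population of 10
    chromosomes, a 20% per-gene mutation probability, 500 generations,
    two-descriptor models, elitism of one.
    """

    population_size: int = 10
    mutation_rate: float = 0.20
    generations: int = 500
    subset_size: int = 2
    elitism_count: int = 1
    fitness_name: str = "q2_loo"  # or "r2"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.fitness_name not in ("q2_loo", "r2"):
            raise ValueError(f"unknown fitness {self.fitness_name!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisConfig:
    """Full pipeline configuration; round-trips through YAML unchanged."""

    ga: GAConfig = field(default_factory=GAConfig)
    corr_threshold: float = 0.95
    near_constant_max_freq: float = 0.95
    n_train: int = 12
    split_method: str = "ranked"  # or "random"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in (0, 1]")
        if not (0.0 < self.near_constant_max_freq <= 1.0):
            raise ValueError("near_constant_max_freq must be in (0, 1]")
        if self.n_train < 2:
            raise ValueError("n_train must be >= 2")
        if self.split_method not in ("ranked", "random"):
            raise ValueError(f"unknown split method {self.split_method!r}")
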