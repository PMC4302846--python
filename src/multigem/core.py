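"""Core containers for base reconstructions and assembled whole-plant models.

A :class:`BaseGEM` is a single-tissue genome-scale reconstruction: metabolites,
reactions with signed stoichiometry and flux bounds.  A
:class:`WholePlantModel` is the assembled multi-tissue, multi-period system in
which every column (flux) carries a provenance record tying it back to a base
reaction in a given tissue and period, or to a pool transporter/accumulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

DEFAULT_BOUND = 1000.0

#: separator used when suffixing replicated ids; double underscore keeps the
#: mapping reversible as long as base ids avoid "__", which the readers check.
SEP = "__"


class ModelError(ValueError):
    """Raised for structurally invalid models or references."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    is_exchange: bool = False
    gene_rule: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        for met, coef in self.stoichiometry.items():
            if not np.isfinite(coef) or coef == 0.0:
                raise ModelError(
                    f"reaction {self.id!r}: coefficient for {met!r} must be "
                    f"finite and non-zero, got {coef!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound


class BaseGEM:
    """A base reconstruction: the internal matrix S plus exchange columns E.

    Metabolite ids index the rows, reaction ids the columns.  Ids are opaque
    tokens; replication suffixes are owned by the assembler, so base ids must
    not contain the reserved ``__`` separator.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        annotations: Mapping[str, str] | None = None,
    ) -> None:
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.annotations: dict[str, str] = dict(annotations or {})
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._validate()

    def _validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelError("duplicate reaction ids")
        for ident in list(self._met_index) + list(self._rxn_index):
            if SEP in ident:
                raise ModelError(
                    f"id {ident!r} contains the reserved separator {SEP!r}"
                )
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in self._met_index:
                    raise ModelError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise ModelError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ModelError(f"unknown reaction {rxn_id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Signed stoichiometric matrix, rows = metabolites, cols = reactions."""
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                rows.append(self._met_index[met])
                cols.append(j)
                vals.append(coef)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<BaseGEM {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# -- assembled whole-plant system ---------------------------------------


@dataclass(frozen=True)
class FluxInfo:
    """Provenance of one column of the assembled matrix.

    kind is one of ``reaction`` (replicated internal reaction, S block),
    ``exchange`` (replicated environment exchange, E block), ``transport``
    (tissue <-> common-pool transporter, T block) and ``accumulation``
    (tissue -> storage-pool flux, A block).
    """

    kind: str
    base_reaction: str | None = None
    tissue: str | None = None
    period: str | None = None
    pool: str | None = None
    species: str | None = None
    direction: str | None = None  # transport only: "export" | "import"


ROW_TISSUE = "tissue_metabolite"
ROW_COMMON_POOL = "common_pool"
ROW_STORAGE_POOL = "storage_pool"


@dataclass
class Column:
    id: str
    stoich: dict[str, float]
    lb: float
    ub: float
    objective: float
    info: FluxInfo


@dataclass
class RowInfo:
    kind: str
    species: str | None = None
    tissue: str | None = None
    period: str | None = None
    pool: str | None = None


class WholePlantModel:
    """The assembled block system: tissue replicas x periods + pool rows.

    Rows are replicated tissue metabolites, one common-pool balance row per
    (pool, species, period), and one storage-pool balance row per stored
    species.  Columns carry a :class:`FluxInfo` provenance record each.
    """

    def __init__(self, base: BaseGEM) -> None:
        self.base = base
        self.row_ids: list[str] = []
        self.row_info: dict[str, RowInfo] = {}
        self.columns: list[Column] = []
        self._row_index: dict[str, int] = {}
        self._col_index: dict[str, int] = {}

    # -- construction ----------------------------------------------------
    def add_row(self, row_id: str, info: RowInfo) -> None:
        if row_id in self._row_index:
            raise ModelError(f"duplicate row {row_id!r}")
        self._row_index[row_id] = len(self.row_ids)
        self.row_ids.append(row_id)
        self.row_info[row_id] = info

    def add_column(
        self,
        col_id: str,
        stoich: dict[str, float],
        lb: float,
        ub: float,
        info: FluxInfo,
        objective: float = 0.0,
    ) -> None:
        if col_id in self._col_index:
            raise ModelError(f"duplicate column {col_id!r}")
        if lb > ub:
            raise ModelError(f"column {col_id!r}: lb {lb} > ub {ub}")
        for row in stoich:
            if row not in self._row_index:
                raise ModelError(f"column {col_id!r} references unknown row {row!r}")
        self._col_index[col_id] = len(self.columns)
        self.columns.append(Column(col_id, dict(stoich), lb, ub, objective, info))

    # -- views -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    @property
    def column_ids(self) -> list[str]:
        return [c.id for c in self.columns]

    def column(self, col_id: str) -> Column:
        try:
            return self.columns[self._col_index[col_id]]
        except KeyError:
            raise ModelError(f"unknown column {col_id!r}") from None

    def column_index(self, col_id: str) -> int:
        try:
            return self._col_index[col_id]
        except KeyError:
            raise ModelError(f"unknown column {col_id!r}") from None

    @property
    def flux_index(self) -> dict[str, FluxInfo]:
        """Map column id -> provenance record."""
        return {c.id: c.info for c in self.columns}

    def matrix(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for j, col in enumerate(self.columns):
            for row, coef in col.stoich.items():
                rows.append(self._row_index[row])
                cols.append(j)
                vals.append(coef)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_rows, self.n_cols)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([c.lb for c in self.columns])
        ub = np.array([c.ub for c in self.columns])
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        return np.array([c.objective for c in self.columns])

    def set_bounds(self, col_id: str, lb: float, ub: float) -> None:
        if lb > ub:
            raise ModelError(f"column {col_id!r}: lb {lb} > ub {ub}")
        col = self.column(col_id)
        col.lb, col.ub = lb, ub

    def find_columns(self, **selectors: str | None) -> list[str]:
        """Column ids whose provenance matches all given FluxInfo fields."""
        out = []
        for col in self.columns:
            if all(getattr(col.info, k) == v for k, v in selectors.items()):
                out.append(col.id)
        return out

    def provenance_table(self):
        """Full provenance as a pandas DataFrame (one row per column)."""
        import pandas as pd

        records = []
        for col in self.columns:
            rec = {"flux": col.id, "lb": col.lb, "ub": col.ub,
                   "objective": col.objective}
            rec.update(col.info.__dict__)
            records.append(rec)
        return pd.DataFrame(records)

    def copy(self) -> "WholePlantModel":
        clone = WholePlantModel(self.base)
        for rid in self.row_ids:
            info = self.row_info[rid]
            clone.add_row(rid, RowInfo(**info.__dict__))
        for col in self.columns:
            clone.add_column(
                col.id, dict(col.stoich), col.lb, col.ub, col.info, col.objective
            )
        return clone

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<WholePlantModel {self.n_rows} rows x {self.n_cols} columns>"
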