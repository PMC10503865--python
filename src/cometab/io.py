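"""Readers and writers for models, abundance tables, diets, and reports.

Two model dialects are supported:

* **SBML** Level 3 + FBC, read and written through cobrapy. Extra linear
  constraint rows (coupling constraints) are not part of SBML-FBC core and
  are therefore dropped on SBML export; use the tabular dialect for models
  that carry them.
* **tabular** — a directory of flat TSVs (``metabolites.tsv``,
  ``reactions.tsv`` with stoichiometry encoded ``met:coef;met:coef``,
  ``bounds.tsv``, plus optional ``constraints.tsv`` and ``meta.tsv``).
  Hand-writable and diffable, used for all toy fixtures.

Abundance tables are read species-per-row (the usual gOTU layout) and held
in memory as sample × species. Diet files are two-column TSVs
``metabolite<TAB>flux_mmol_per_day``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BOUND,
    LinearConstraint,
    Metabolite,
    Reaction,
    StoichiometricModel,
    split_compartment,
)
from .errors import FormatError, ValidationError

_REL_TOL = 1e-9


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Sample × species abundance matrix.

    ``mode`` is ``"counts"`` (raw gOTU read counts) or ``"relative"``
    (each sample row sums to one).
    """

    values: pd.DataFrame  # index = samples, columns = species
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown abundance mode {self.mode!r}")
        self.validate()

    @property
    def samples(self) -> List[str]:
        return list(self.values.index)

    @property
    def species(self) -> List[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.values.shape[1] == 0:
            raise ValidationError("no species in abundance table")
        if (self.values.values < 0).any():
            raise ValidationError("abundance table contains negative entries")
        if self.mode == "relative":
            sums = self.values.sum(axis=1)
            bad = sums[(sums - 1.0).abs() > 1e-6]
            if len(bad):
                raise ValidationError(
                    f"relative abundances must sum to 1 per sample; offending "
                    f"samples: {list(bad.index)[:5]}"
                )

    def normalize(self) -> "AbundanceTable":
        """Return the relative-abundance version (sum of reads per sample = 1).

        Idempotent: normalising a relative table returns an equal table.
        """
        totals = self.values.sum(axis=1)
        zero = totals[totals <= 0]
        if len(zero):
            raise ValidationError(
                f"samples with zero total reads cannot be normalised: {list(zero.index)}"
            )
        rel = self.values.div(totals, axis=0)
        return AbundanceTable(values=rel, mode="relative")


def read_abundances(path: str | Path, mode: str = "counts") -> AbundanceTable:
    """Read a species-per-row TSV into an :class:`AbundanceTable`.

    Rows sharing a species id are summed (merging gOTUs that map to the same
    species); negative entries are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse abundance table {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError("no species in abundance table")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"non-numeric entries in abundance table {path}")
    df = df.groupby(level=0, sort=False).sum()
    table = AbundanceTable(values=df.T, mode=mode)
    return table


def write_abundances(table: AbundanceTable, path: str | Path) -> None:
    table.values.T.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# diets
# ---------------------------------------------------------------------------

@dataclass
class DietSpec:
    """Metabolite (base id, no compartment tag) → uptake flux in mmol/person/day."""

    entries: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, flux in self.entries.items():
            if "[" in met:
                raise ValidationError(
                    f"diet metabolite {met!r} carries a compartment tag; use base ids"
                )
            if flux < 0:
                raise ValidationError(f"negative diet flux for {met!r}")

    def copy(self) -> "DietSpec":
        return DietSpec(entries=dict(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, met: str, default: float = 0.0) -> float:
        return self.entries.get(met, default)


def read_diet(path: str | Path) -> DietSpec:
    """Read a two-column TSV ``metabolite<TAB>flux``; duplicates are an error."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["metabolite", "flux"], skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return DietSpec()
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse diet file {path}: {exc}") from exc
    if len(df) == 0:
        return DietSpec()
    # tolerate a header row
    if str(df.iloc[0, 0]).lower() in ("metabolite", "met", "compound"):
        df = df.iloc[1:]
    if df.empty:
        return DietSpec()
    dup = df["metabolite"][df["metabolite"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"duplicate diet entries are ambiguous: {sorted(set(dup))}"
        )
    try:
        fluxes = df["flux"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric flux in diet file {path}") from exc
    return DietSpec(entries=dict(zip(df["metabolite"].astype(str), fluxes)))


def write_diet(diet: DietSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite\tflux_mmol_per_day\n")
        for met in sorted(diet.entries):
            fh.write(f"{met}\t{diet.entries[met]:.10g}\n")


# ---------------------------------------------------------------------------
# stoichiometric models — tabular dialect
# ---------------------------------------------------------------------------

def _encode_map(d: Dict[str, float]) -> str:
    return ";".join(f"{k}:{v:.12g}" for k, v in d.items())


def _decode_map(text: str, what: str) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise FormatError(f"malformed {what} entry {part!r}")
        key, _, val = part.rpartition(":")
        try:
            out[key] = float(val)
        except ValueError as exc:
            raise FormatError(f"malformed {what} coefficient in {part!r}") from exc
    return out


def write_model(model: StoichiometricModel, path: str | Path, format: str = "tabular") -> None:
    """Write a model; ``format`` is ``"tabular"`` (directory of TSVs) or ``"sbml"``."""
    if format == "sbml":
        _write_sbml(model, path)
        return
    if format != "tabular":
        raise ValidationError(f"unknown model format {format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tcompartment\n")
        for m in model.metabolites.values():
            fh.write(f"{m.id}\t{m.name}\t{m.compartment}\n")
    with open(path / "reactions.tsv", "w") as fh:
        fh.write("id\tname\tsubsystem\tstoichiometry\n")
        for r in model.reactions.values():
            fh.write(f"{r.id}\t{r.name}\t{r.subsystem}\t{_encode_map(r.stoichiometry)}\n")
    with open(path / "bounds.tsv", "w") as fh:
        fh.write("reaction\tlower\tupper\n")
        for r in model.reactions.values():
            fh.write(f"{r.id}\t{r.lower_bound:.12g}\t{r.upper_bound:.12g}\n")
    if model.extra_constraints:
        with open(path / "constraints.tsv", "w") as fh:
            fh.write("name\tcoefficients\tsense\trhs\n")
            for c in model.extra_constraints:
                fh.write(f"{c.name}\t{_encode_map(c.coefficients)}\t{c.sense}\t{c.rhs:.12g}\n")
    with open(path / "meta.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"id\t{model.id}\n")
        if model.objective is not None:
            fh.write(f"objective\t{model.objective}\n")
            fh.write(f"objective_sense\t{model.objective_sense}\n")


def read_model(path: str | Path, format: str = "tabular") -> StoichiometricModel:
    """Read a model written by :func:`write_model`.

    Bounds absent from the file default to ±1000 (COBRA convention); dangling
    metabolite references raise a validation error naming the reaction.
    """
    if format == "sbml":
        return _read_sbml(path)
    if format != "tabular":
        raise ValidationError(f"unknown model format {format!r}")
    path = Path(path)
    if not (path / "reactions.tsv").exists():
        raise FormatError(f"{path} is not a tabular model directory (no reactions.tsv)")
    mets = pd.read_csv(path / "metabolites.tsv", sep="\t", keep_default_na=False)
    rxns = pd.read_csv(path / "reactions.tsv", sep="\t", keep_default_na=False)
    model = StoichiometricModel(id=str(path.name))
    for _, row in mets.iterrows():
        model.add_metabolite(
            Metabolite(id=row["id"], name=row.get("name", ""), compartment=row.get("compartment") or None)
        )
    bounds: Dict[str, tuple] = {}
    bounds_path = path / "bounds.tsv"
    if bounds_path.exists():
        bt = pd.read_csv(bounds_path, sep="\t")
        bounds = {r["reaction"]: (float(r["lower"]), float(r["upper"])) for _, r in bt.iterrows()}
    for _, row in rxns.iterrows():
        stoich = _decode_map(row["stoichiometry"], "stoichiometry")
        lb, ub = bounds.get(row["id"], (-DEFAULT_BOUND, DEFAULT_BOUND))
        rxn = Reaction(
            id=row["id"], stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            name=row.get("name", ""), subsystem=row.get("subsystem", ""),
        )
        model.add_reaction(rxn)  # raises on dangling metabolite references
    cons_path = path / "constraints.tsv"
    if cons_path.exists():
        ct = pd.read_csv(cons_path, sep="\t", keep_default_na=False)
        for _, row in ct.iterrows():
            model.add_constraint(
                LinearConstraint(
                    coefficients=_decode_map(row["coefficients"], "constraint"),
                    sense=row["sense"], rhs=float(row["rhs"]), name=row["name"],
                )
            )
    meta_path = path / "meta.tsv"
    if meta_path.exists():
        mt = pd.read_csv(meta_path, sep="\t", keep_default_na=False)
        meta = dict(zip(mt["key"], mt["value"]))
        model.id = meta.get("id", model.id)
        if "objective" in meta:
            model.objective = meta["objective"]
            model.objective_sense = meta.get("objective_sense", "max")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# stoichiometric models — SBML via cobrapy
# ---------------------------------------------------------------------------

def to_cobra(model: StoichiometricModel):
    """Convert to a cobrapy Model (extra constraint rows are dropped)."""
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, name=r.name, subsystem=r.subsystem,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cmets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    if model.objective is not None:
        cm.objective = model.objective
        cm.objective_direction = model.objective_sense
    return cm


def from_cobra(cm) -> StoichiometricModel:
    """Convert a cobrapy Model into a :class:`StoichiometricModel`."""
    model = StoichiometricModel(id=cm.id or "model")
    for m in cm.metabolites:
        model.add_metabolite(
            Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or None)
        )
    for r in cm.reactions:
        model.add_reaction(
            Reaction(
                id=r.id,
                stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
                lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                name=r.name or "", subsystem=r.subsystem or "",
            )
        )
    return model


def _write_sbml(model: StoichiometricModel, path: str | Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


def _read_sbml(path: str | Path) -> StoichiometricModel:
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FormatError(f"SBML file {path} does not exist")
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse SBML file {path}: {exc}") from exc
    model = from_cobra(cm)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(obj, path: str | Path) -> None:
    """Write a report object.

    DataFrames go to TSV with a stable column order; dataclasses and dicts go
    to JSON with sorted keys (deterministic output byte-for-byte).
    """
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", float_format="%.10g", index=True)
    elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(obj), fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    elif isinstance(obj, dict):
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    else:
        raise ValidationError(f"cannot serialise report of type {type(obj).__name__}")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON serialisable: {type(o).__name__}")
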