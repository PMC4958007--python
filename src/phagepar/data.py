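"""Mutation-by-isolate data model, tabular I/O, QC and event counting.

The unit of replication is the *well*: one evolving population founded from
a known ancestral background (a single first-step mutation on the wild-type
genome).  Each well contributes a handful of sequenced endpoint isolates,
and each isolate is recorded as the set of de novo mutations it carries
relative to the well's ancestor.  A *reversion* — loss of the background
mutation — is represented as an ordinary mutation key (the back-mutation at
the background site), so every analysis can include or exclude reversions
with a flag.

Canonical interchange format: UTF-8 TSV with columns
``isolate_id  well_id  background_id  mutation_key``, one row per
isolate x mutation, and a sentinel row (mutation_key ``.``) for isolates
with no de novo mutations.  An XLSX reader with the same column layout is
provided; the TSV is canonical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .annotation import (
    GenomeAnnotation,
    MutationRecord,
    annotate_mutation,
    parse_mutation_key,
    reversion_key,
)

SENTINEL = "."

TSV_COLUMNS = ["isolate_id", "well_id", "background_id", "mutation_key"]


class DataConsistencyError(ValueError):
    """Raised when a table violates the dataset invariants."""


@dataclass(frozen=True)
class IsolateGenotype:
    """De novo mutation set of one sequenced isolate."""

    isolate_id: str
    well_id: str
    mutations: frozenset[str]

    def background_present(self, background_reversion_key: str) -> bool:
        return background_reversion_key not in self.mutations


@dataclass
class WellRecord:
    well_id: str
    background_id: str
    isolates: list[IsolateGenotype] = field(default_factory=list)
    qc_pass: bool = True

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)


@dataclass
class Dataset:
    """All wells of one experiment plus the shared mutation catalog.

    ``background_catalog`` maps a background id (e.g. ``"F416"``) to the
    mutation key of that first-step mutation on the wild-type genome.
    """

    wells: list[WellRecord]
    mutation_catalog: dict[str, MutationRecord]
    annotation: GenomeAnnotation
    background_catalog: dict[str, str]

    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]

    @property
    def n_isolates(self) -> int:
        return sum(w.n_isolates for w in self.wells)

    def well(self, well_id: str) -> WellRecord:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def background_of(self, well_id: str) -> str:
        return self.well(well_id).background_id

    @property
    def reversion_keys(self) -> dict[str, str]:
        """background_id -> key of the back-mutation at its site."""
        return {b: reversion_key(k) for b, k in self.background_catalog.items()}

    @property
    def all_reversion_keys(self) -> frozenset[str]:
        return frozenset(self.reversion_keys.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            for iso in w.isolates:
                keys = sorted(iso.mutations) or [SENTINEL]
                for k in keys:
                    rows.append((iso.isolate_id, w.well_id, w.background_id, k))
        return pd.DataFrame(rows, columns=TSV_COLUMNS)


def _dataset_from_frame(df: pd.DataFrame, annotation: GenomeAnnotation,
                        background_catalog: dict[str, str]) -> Dataset:
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataConsistencyError(f"missing columns: {missing}")
    df = df[TSV_COLUMNS].astype(str)

    iso_wells = df.groupby("isolate_id")["well_id"].nunique()
    bad = iso_wells[iso_wells > 1]
    if len(bad):
        raise DataConsistencyError(
            f"isolates assigned to more than one well: {sorted(bad.index)}"
        )
    well_bgs = df.groupby("well_id")["background_id"].nunique()
    bad = well_bgs[well_bgs > 1]
    if len(bad):
        raise DataConsistencyError(
            f"wells with more than one background: {sorted(bad.index)}"
        )
    unknown_bg = set(df["background_id"]) - set(background_catalog)
    if unknown_bg:
        raise DataConsistencyError(f"unknown background ids: {sorted(unknown_bg)}")

    catalog: dict[str, MutationRecord] = {}
    wells: dict[str, WellRecord] = {}
    for (well_id, background_id), g in df.groupby(["well_id", "background_id"], sort=True):
        well = WellRecord(well_id=well_id, background_id=background_id)
        for isolate_id, gi in g.groupby("isolate_id", sort=True):
            keys = set()
            for row_i, key in gi["mutation_key"].items():
                if key == SENTINEL:
                    continue
                try:
                    pos, fb, tb = parse_mutation_key(key)
                except ValueError as exc:
                    raise DataConsistencyError(f"row {row_i}: {exc}") from exc
                if key not in catalog:
                    try:
                        catalog[key] = annotate_mutation(pos, fb, tb, annotation)
                    except ValueError as exc:
                        raise DataConsistencyError(f"row {row_i}: {exc}") from exc
                keys.add(catalog[key].key)
            well.isolates.append(IsolateGenotype(isolate_id, well_id, frozenset(keys)))
        wells[well_id] = well
    return Dataset(
        wells=[wells[w] for w in sorted(wells)],
        mutation_catalog=catalog,
        annotation=annotation,
        background_catalog=dict(background_catalog),
    )


def read_mutation_table(path, annotation: GenomeAnnotation,
                        background_catalog: dict[str, str]) -> Dataset:
    """Read the canonical mutation-by-isolate TSV into a :class:`Dataset`."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return _dataset_from_frame(df, annotation, background_catalog)


def read_mutation_xlsx(path, annotation: GenomeAnnotation,
                       background_catalog: dict[str, str],
                       sheet_name=0) -> Dataset:
    """Read an XLSX export with the same column layout as the TSV."""
    df = pd.read_excel(path, sheet_name=sheet_name, dtype=str)
    return _dataset_from_frame(df, annotation, background_catalog)


def write_mutation_table(dataset: Dataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def apply_well_qc(dataset: Dataset, min_isolates: int = 4) -> Dataset:
    """Drop wells with fewer than ``min_isolates`` sequenced isolates.

    Sparse wells give unstable mutation-set unions, so wells with too few
    isolates are removed before any analysis.  Idempotent; the default of 4
    keeps wells with at least four isolates.
    """
    if min_isolates < 1:
        raise ValueError("min_isolates must be >= 1")
    kept = [replace(w, qc_pass=True) for w in dataset.wells
            if w.n_isolates >= min_isolates]
    observed = set()
    for w in kept:
        for iso in w.isolates:
            observed |= iso.mutations
    catalog = {k: v for k, v in dataset.mutation_catalog.items() if k in observed}
    return Dataset(
        wells=kept,
        mutation_catalog=catalog,
        annotation=dataset.annotation,
        background_catalog=dict(dataset.background_catalog),
    )


def classify_reversions(dataset: Dataset) -> dict[str, bool]:
    """Flag each well for whether any isolate carries the back-mutation
    restoring the wild-type base at its own background site."""
    out = {}
    for w in dataset.wells:
        if w.background_id not in dataset.background_catalog:
            raise DataConsistencyError(
                f"well {w.well_id}: unknown background {w.background_id!r}"
            )
        rk = reversion_key(dataset.background_catalog[w.background_id])
        out[w.well_id] = any(rk in iso.mutations for iso in w.isolates)
    return out


def well_mutation_set(well: WellRecord, include_reversions: bool = True,
                      reversion_keys: frozenset[str] = frozenset()) -> frozenset[str]:
    """Union of de novo mutation keys over a well's isolates.

    Wells, not isolates, are the unit of between-replicate comparison, so a
    well's mutation complement is the union over its sequenced isolates.
    """
    if not well.isolates:
        raise ValueError(f"well {well.well_id} has no isolates")
    s = frozenset().union(*(iso.mutations for iso in well.isolates))
    if not include_reversions:
        s -= reversion_keys
    return frozenset(s)


def count_mutations_and_events(dataset: Dataset, include_reversions: bool = True
                               ) -> tuple[int, int, dict[str, int]]:
    """Unique mutations, mutational events, and per-mutation well counts.

    A mutation observed in k wells contributes k *events*; unique counts
    each mutation once regardless of how many wells it appears in.
    """
    counts: dict[str, int] = {}
    rev = dataset.all_reversion_keys
    for w in dataset.wells:
        for k in well_mutation_set(w, include_reversions, rev):
            counts[k] = counts.get(k, 0) + 1
    return len(counts), sum(counts.values()), counts


@dataclass(frozen=True)
class ContaminationFlag:
    well_id: str
    isolate_id: str
    foreign_backgrounds: tuple[str, ...]


def flag_contamination(dataset: Dataset) -> dict[str, list[ContaminationFlag]]:
    """Screen wells for cross-well contamination signatures.

    An isolate is suspicious when it (1) lacks its own well's background
    mutation (i.e. carries the back-mutation at the background site) and
    (2) carries the first-step mutation of a *different* background.  Wells
    with at least one such isolate are reported together with the foreign
    background(s) involved.  Sequence-forensic criteria that require
    cross-well read comparison are out of scope here.
    """
    rev_by_bg = dataset.reversion_keys
    flags: dict[str, list[ContaminationFlag]] = {}
    for w in dataset.wells:
        own_rev = rev_by_bg[w.background_id]
        for iso in w.isolates:
            if own_rev not in iso.mutations:
                continue  # own background still present
            foreign = tuple(sorted(
                b for b, key in dataset.background_catalog.items()
                if b != w.background_id and key in iso.mutations
            ))
            if foreign:
                flags.setdefault(w.well_id, []).append(
                    ContaminationFlag(w.well_id, iso.isolate_id, foreign)
                )
    return flags


def presence_matrix(dataset: Dataset, include_reversions: bool = False) -> pd.DataFrame:
    """Well x mutation boolean presence matrix (present in >= 1 isolate)."""
    rev = dataset.all_reversion_keys
    sets = {w.well_id: well_mutation_set(w, include_reversions, rev)
            for w in dataset.wells}
    keys = sorted(set().union(*sets.values())) if sets else []
    df = pd.DataFrame(False, index=sorted(sets), columns=keys, dtype=bool)
    for wid, s in sets.items():
        df.loc[wid, sorted(s)] = True
    return df


def isolate_presence_matrix(dataset: Dataset, include_reversions: bool = False
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Isolate x mutation boolean matrix plus isolate -> well mapping."""
    rev = dataset.all_reversion_keys
    rows = {}
    wells = {}
    for w in dataset.wells:
        for iso in w.isolates:
            muts = iso.mutations if include_reversions else iso.mutations - rev
            rows[iso.isolate_id] = muts
            wells[iso.isolate_id] = w.well_id
    keys = sorted(set().union(*rows.values())) if rows else []
    df = pd.DataFrame(False, index=sorted(rows), columns=keys, dtype=bool)
    for iid, s in rows.items():
        df.loc[iid, sorted(s)] = True
    return df, pd.Series(wells).loc[df.index]


def warn_if(cond: bool, message: str) -> None:
    if cond:
        warnings.warn(message, stacklevel=3)
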