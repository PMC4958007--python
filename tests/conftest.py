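import numpy as np
import pytest

from phagepar.annotation import GenomeAnnotation
from phagepar.data import Dataset, IsolateGenotype, WellRecord
from phagepar.simulate import (
    SimConfig,
    _catalog_keys,
    study_preset,
    synthetic_annotation,
)


@pytest.fixture(scope="session")
def annotation() -> GenomeAnnotation:
    return synthetic_annotation()


@pytest.fixture(scope="session")
def preset() -> SimConfig:
    return study_preset()


def make_dataset(well_sets: dict[str, list[set[str]]],
                 backgrounds: dict[str, str],
                 background_catalog: dict[str, str],
                 annotation: GenomeAnnotation) -> Dataset:
    """Hand-build a Dataset from per-well lists of isolate mutation sets."""
    from phagepar.annotation import parse_mutation_key
    from phagepar.annotation import annotate_mutation

    wells = []
    catalog = {}
    for wid, isolates in well_sets.items():
        w = WellRecord(well_id=wid, background_id=backgrounds[wid])
        for i, muts in enumerate(isolates):
            w.isolates.append(
                IsolateGenotype(f"{wid}_i{i + 1}", wid, frozenset(muts)))
            for k in muts:
                if k not in catalog:
                    catalog[k] = annotate_mutation(
                        *parse_mutation_key(k), annotation)
        wells.append(w)
    return Dataset(wells=wells, mutation_catalog=catalog,
                   annotation=annotation,
                   background_catalog=dict(background_catalog))


def key_at(annotation: GenomeAnnotation, pos: int, to: str | None = None) -> str:
    """A valid mutation key at a genome position of the given annotation."""
    from phagepar.annotation import format_mutation_key

    fb = annotation.ancestral_base(pos)
    tb = to or next(b for b in "acgt" if b != fb)
    return format_mutation_key(pos, fb, tb)


def null_sim_config(annotation: GenomeAnnotation, n_mutations: int = 40,
                    n_backgrounds: int = 4, wells_per_background: int = 4,
                    isolates_per_well: int = 4, incidence: float = 0.10,
                    mean_mutations: float = 4.0,
                    delta: dict | None = None) -> SimConfig:
    """A small background-neutral configuration (no planted effects, no
    reversions, no exclusivity) for calibration experiments."""
    rng = np.random.default_rng(99)
    positions: list[int] = []
    used: set[int] = set()
    while len(positions) < n_mutations + n_backgrounds:
        p = int(rng.integers(1, annotation.genome_length + 1))
        if p not in used:
            used.add(p)
            positions.append(p)
    keys = _catalog_keys(annotation, positions[:n_mutations])
    bg_keys = _catalog_keys(annotation, positions[n_mutations:])
    return SimConfig(
        background_catalog={f"b{i}": k for i, k in enumerate(bg_keys)},
        mutation_keys=keys,
        incidence=np.full(n_mutations, incidence),
        annotation=annotation,
        wells_per_background=wells_per_background,
        isolates_per_well=isolates_per_well,
        mean_mutations=mean_mutations,
        m_min=1,
        m_max=min(8, n_mutations),
        delta=delta or {},
    )
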