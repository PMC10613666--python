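import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metapaseflow import PrecursorTable, SampleDesign
from metapaseflow.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_precursors(rows):
    """rows: iterable of (precursor_id, seq, pg, run, intensity, q, pg_q[, origin])."""
    recs = []
    for r in rows:
        rec = dict(
            precursor_id=r[0],
            stripped_sequence=r[1],
            protein_group=r[2],
            run_id=r[3],
            intensity=r[4],
            precursor_q=r[5],
            protein_group_q=r[6],
            origin=r[7] if len(r) > 7 else "microbial",
        )
        recs.append(rec)
    return PrecursorTable(pd.DataFrame(recs))


def make_design(n_subjects=4, condition="SNI", timepoints=("Pre", "14D"), batch="b1"):
    rows = []
    for i in range(n_subjects):
        for tp in timepoints:
            rows.append(
                dict(
                    run_id=f"{condition}_m{i + 1}_{tp}",
                    subject=f"{condition}_m{i + 1}",
                    condition=condition,
                    timepoint=tp,
                    batch=batch,
                    replicate=1,
                )
            )
    return SampleDesign(pd.DataFrame(rows))


SMALL_TAXA = {
    "superkingdom": 1,
    "kingdom": 1,
    "phylum": 2,
    "class": 2,
    "order": 2,
    "family": 3,
    "genus": 4,
    "species": 6,
}


def small_config(seed=11, **overrides):
    base = dict(
        n_taxa_per_rank=dict(SMALL_TAXA),
        n_proteins_per_species=2,
        n_peptides_per_protein=3,
        n_host_proteins=2,
        n_k_numbers=10,
        n_pathways=4,
    )
    base.update(overrides)
    return SimConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_dataset(small_config())
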