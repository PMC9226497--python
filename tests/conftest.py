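import numpy as np
import pandas as pd
import pytest

from hdxpipe.io import CANONICAL_COLUMNS, Peptide, UptakeTable
from hdxpipe.synth import (generate_ground_truth, generate_peptide_map,
                           simulate_uptake)


def make_table(rows, metadata=None) -> UptakeTable:
    """Build an UptakeTable from (protein, state, start, end, sequence,
    exposure_s, uptake_Da, sd_Da, n_reps) tuples."""
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return UptakeTable(df, metadata)


def curve_rows(protein, state, start, end, sequence, points, n_reps=3):
    """Rows for one peptide; points = [(t, uptake, sd), ...]."""
    return [(protein, state, start, end, sequence, t, d, sd, n_reps)
            for t, d, sd in points]


@pytest.fixture(scope="session")
def truth():
    """40-residue two-state landscape: protection planted in 10-20, a fully
    exposed template region at 30-36."""
    return generate_ground_truth(
        40, delta_regions=[(10, 20, 1.0)], exposed_regions=[(30, 36)],
        seed=11)


@pytest.fixture(scope="session")
def peptide_map(truth):
    return generate_peptide_map(truth.sequence, mean_length=9,
                                mean_overlap=3, seed=11,
                                include_spans=[(30, 36)])


@pytest.fixture(scope="session")
def clean_tables(truth, peptide_map):
    """Noise-free, back-exchange-free tables for exact comparisons."""
    return simulate_uptake(truth, peptide_map, noise_sd=0.0,
                           backexchange_frac=0.0, n_reps=1, seed=11)


@pytest.fixture(scope="session")
def noisy_tables(truth, peptide_map):
    return simulate_uptake(truth, peptide_map, noise_sd=0.05,
                           backexchange_frac=0.25, n_reps=3, seed=11)


def write_multimodel_pdb(path, frames, resnames, atom_names, elements,
                         res_ids, chain="A"):
    """Write a multi-MODEL PDB from per-frame coordinate arrays."""
    lines = []
    for mi, coords in enumerate(frames, start=1):
        lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for (x, y, z), rn, an, el, ri in zip(coords, resnames, atom_names,
                                             elements, res_ids):
            record = "HETATM" if rn == "HOH" else "ATOM  "
            name = an if len(an) == 4 else f" {an:<3s}"
            lines.append(
                f"{record}{serial:5d} {name}{'':1s}{rn:<3s} {chain}"
                f"{ri:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {el:>2s}")
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
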