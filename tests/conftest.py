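import numpy as np
import pandas as pd
import pytest

from pufascreen.alignment import AlignedRecord, ParalogAlignment
from pufascreen.simulate import ConstructSpec, TraceGenConfig, generate_trace_set
from pufascreen.topology import default_topology
from pufascreen.traces import BACKGROUND_ID


@pytest.fixture
def toy_alignment() -> ParalogAlignment:
    """The three-sequence toy where positions 4 and 8 are group-specific."""
    return ParalogAlignment(
        records=[
            AlignedRecord("Dmel", "TRPL", "ACDEFGHIKL"),
            AlignedRecord("Dmel", "TRPgamma", "ACDEFGHIKL"),
            AlignedRecord("Dmel", "TRP", "ACDQFGHMKL"),
        ],
        reference_id="Dmel|TRPL",
    )


@pytest.fixture(scope="session")
def topology():
    return default_topology()


def make_alignment(sequences: dict[str, str], reference_id: str) -> ParalogAlignment:
    """Build a ParalogAlignment from '<species>|<paralog>' -> sequence."""
    records = [
        AlignedRecord(*key.split("|", 1), seq) for key, seq in sequences.items()
    ]
    return ParalogAlignment(records=records, reference_id=reference_id)


def random_alignment(rng: np.random.Generator, n_columns: int, gap_rate: float = 0.1):
    """Random small alignment over 2 sensitive + 1 insensitive paralogs x 3 species.

    Returns (alignment, id->sequence dict, sensitive ids, insensitive ids).
    Drawn from a reduced alphabet so differential columns actually occur.
    """
    alphabet = np.array(list("ACDE-"))
    species = ["sp1", "sp2", "sp3"]
    paralogs = ["TRPL", "TRPgamma", "TRP"]
    probs = np.array([(1 - gap_rate) / 4] * 4 + [gap_rate])
    sequences = {}
    for paralog in paralogs:
        for sp in species:
            seq = "".join(rng.choice(alphabet, size=n_columns, p=probs))
            sequences[f"{sp}|{paralog}"] = seq
    # the reference must have at least one non-gap column
    if set(sequences["sp1|TRPL"]) == {"-"}:
        sequences["sp1|TRPL"] = "A" + sequences["sp1|TRPL"][1:]
    aln = make_alignment(sequences, "sp1|TRPL")
    sens = [k for k in sequences if k.endswith("TRPL") or k.endswith("TRPgamma")]
    insens = [k for k in sequences if k.endswith("|TRP")]
    return aln, sequences, sens, insens


def small_trace_config(**overrides) -> TraceGenConfig:
    """A quick two-construct recording (WT + one half-amplitude mutant)."""
    defaults = dict(
        constructs=[
            ConstructSpec("TRPL-WT", "ETYA", 1.0, 20),
            ConstructSpec("F467Y", "ETYA", 0.3, 20),
        ],
        noise_sd=0.0,
        responder_fraction=1.0,
        seed=7,
    )
    defaults.update(overrides)
    return TraceGenConfig(**defaults)


@pytest.fixture
def noiseless_trace_set():
    return generate_trace_set(small_trace_config())


def ratio_frame(
    construct="C1",
    ligand="ETYA",
    times=(0.0, 1.0, 2.0, 3.0),
    cells=None,
    background=(0.0, 0.0),
    yfp=100.0,
):
    """Hand-build a tidy trace frame from per-cell (f340, f380) series."""
    cells = cells or {"c1": ([200.0] * len(times), [100.0] * len(times))}
    rows = []
    for cell, (f340, f380) in cells.items():
        for t, a, b in zip(times, f340, f380):
            rows.append((construct, ligand, cell, t, a, b, yfp))
    for t in times:
        rows.append((construct, ligand, BACKGROUND_ID, t, background[0], background[1], np.nan))
    return pd.DataFrame(
        rows, columns=["construct", "ligand", "cell_id", "time_s", "f340", "f380", "yfp"]
    )
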