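from pathlib import Path

import pytest

from venomics.synthetic_data import default_config, generate_dataset

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toxin_cds():
    """Full-length venom toxin coding sequences (name -> nucleotide string)."""
    records = {}
    name = None
    chunks = []
    for line in (DATA_DIR / "venom_toxin_cds.fasta").read_text().splitlines():
        if line.startswith(">"):
            if name:
                records[name] = "".join(chunks)
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name:
        records[name] = "".join(chunks)
    return records


@pytest.fixture(scope="session")
def default_sim():
    """The default three-species simulation at seed 1, with ground truth."""
    return generate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def pipeline_default(tmp_path_factory):
    """One full pipeline run at the default study conditions (seed 7)."""
    from venomics.concordance_report import run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(default_config(seed=7), outdir, seed=7)
    return report, outdir


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down simulation for fast matching/annotation tests."""
    config = default_config(seed=5, depth_gland=20_000, depth_muscle=20_000,
                            n_observed_peptides=40, n_background_genes=8)
    return generate_dataset(config)
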