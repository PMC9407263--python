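import sys
from pathlib import Path

import pytest
from hypothesis import settings

# make the sibling oracles module importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def write_fasta(tmp_path):
    """Write {header: sequence} to a FASTA file and return its path."""

    counter = {"n": 0}

    def _write(records, name=None):
        counter["n"] += 1
        path = tmp_path / (name or f"aln{counter['n']}.fasta")
        with open(path, "w") as fh:
            for header, seq in records.items():
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
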