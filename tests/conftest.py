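import sys
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from silacrnp.quant_io import LabelDesign, ProteinGroupTable


def make_table(rows, design=None, sample_id="test"):
    """Build a ProteinGroupTable from (gene, ratio, peptides, cont, rev) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_symbol",
            "ratio_hl",
            "razor_unique_peptides",
            "is_contaminant",
            "is_reverse",
        ],
    )
    df["group_members"] = df["gene_symbol"]
    return ProteinGroupTable(
        df, sample_id=sample_id, design=design or LabelDesign(heavy="A", light="B")
    )


@pytest.fixture
def tsv_writer(tmp_path):
    """Write a proteinGroups-dialect TSV and return its path."""

    def _write(rows, name="groups.tsv", header=None):
        header = header or [
            "Gene names",
            "Ratio H/L",
            "Razor + unique peptides",
            "Potential contaminant",
            "Reverse",
        ]
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join(str(v) for v in row))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
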