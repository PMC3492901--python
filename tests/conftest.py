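import numpy as np
import pytest

from divscan.alignment import GeneAlignment, filter_sites


def make_alignment(ingroup_rows, outgroup_rows=("",), gene_id="g", **kw):
    """Build a GeneAlignment from plain strings (empty outgroup tuple for
    no-outgroup genes)."""
    ing = np.vstack([np.frombuffer(r.encode(), dtype="S1") for r in ingroup_rows])
    out_rows = [r for r in outgroup_rows if r]
    if out_rows:
        out = np.vstack([np.frombuffer(r.encode(), dtype="S1") for r in out_rows])
    else:
        out = np.empty((0, ing.shape[1]), dtype="S1")
    return GeneAlignment(
        gene_id=gene_id,
        ingroup=ing,
        outgroup=out,
        ingroup_ids=[f"s{i}|{gene_id}" for i in range(len(ingroup_rows))],
        outgroup_ids=[f"Ptaeda|{gene_id}_{i}" for i in range(len(out_rows))],
        **kw,
    )


@pytest.fixture
def worked_matrix():
    """The canonical 4x10 worked example: S=2 at the last two columns,
    haplotype counts 1,1,2, all-ancestral outgroup."""
    aln = make_alignment(
        ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "AAAAAAAATT"],
        ["AAAAAAAAAA"],
        gene_id="worked",
    )
    return aln, filter_sites(aln)
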