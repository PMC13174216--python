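import numpy as np
import pandas as pd
import pytest

from prisge.library import LibraryDesign, PegConstruct, SampleSheet

# the three published spacers programming the EGFR C797S T>A edit
C797S_SPACERS = [
    "ATCACGCAGCTCATGCCCTT",
    "GTTCCCGGACATAGTCCAGG",
    "TGTGTTCCCGGACATAGTCC",
]
C797S_EXTENSIONS = [
    "TCCAGGAGGCTGCCGAAGGGCATGAGCTGC",
    "TTCGGCAGCCTCCTGGACTATGTCCGG",
    "TTCGGCAGCCTCCTGGACTATGTCCGGGAA",
]


def make_construct(cid, spacer, extension, variant="EGFR_C797S",
                   mclass="missense", gene="EGFR", is_control=None):
    return PegConstruct(
        construct_id=cid, spacer=spacer, extension=extension,
        scaffold_id="flip_extend", variant_id=variant, gene=gene,
        variant_label=variant.split("_")[-1], mutation_class=mclass,
        is_control=is_control,
    )


@pytest.fixture
def c797s_library():
    """Three C797S constructs plus two synonymous controls."""
    rng = np.random.default_rng(0)
    letters = np.array(list("ACGT"))
    constructs = [
        make_construct(f"C797S_pg{i+1}", sp, ext)
        for i, (sp, ext) in enumerate(zip(C797S_SPACERS, C797S_EXTENSIONS))
    ]
    for j in range(2):
        sp = "".join(rng.choice(letters, 20))
        ext = "".join(rng.choice(letters, 25))
        constructs.append(
            make_construct(f"SYN_pg{j+1}", sp, ext, variant=f"EGFR_syn{j}",
                           mclass="synonymous")
        )
    return LibraryDesign(constructs)


@pytest.fixture
def simple_sheet():
    rows = []
    for arm in ("vehicle", "osimertinib"):
        for day in (3.0, 19.0):
            for rep in (1, 2):
                rows.append(
                    {"sample_id": f"{arm}_d{day:g}_r{rep}", "replicate": rep,
                     "arm": arm, "day": day, "fastq_r1": "", "fastq_r2": ""}
                )
    return SampleSheet(pd.DataFrame(rows), control_arm="vehicle")
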