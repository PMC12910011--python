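import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from geneburden.cohort_io import SampleRecord, SmallVariant
from geneburden.ontology import parse_obo

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000002
name: level1
is_a: HP:0000001 ! root

[Term]
id: HP:0000003
name: level2
is_a: HP:0000002 ! level1

[Term]
id: HP:0000004
name: level3
is_a: HP:0000003 ! level2

[Term]
id: HP:0000005
name: level4
is_a: HP:0000004 ! level3
"""

# root -> A, B; C has both A and B as parents; D is a leaf under C;
# E is a second leaf directly under A (gives A height 2 via C? no: via E height 1,
# via C->D height 2).
DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000010
name: A
is_a: HP:0000001 ! root

[Term]
id: HP:0000011
name: B
is_a: HP:0000001 ! root

[Term]
id: HP:0000012
name: C
is_a: HP:0000010 ! A
is_a: HP:0000011 ! B

[Term]
id: HP:0000013
name: D
is_a: HP:0000012 ! C

[Term]
id: HP:0000014
name: E
is_a: HP:0000010 ! A
"""


@pytest.fixture
def chain_graph():
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def diamond_graph():
    return parse_obo(DIAMOND_OBO)


def make_sample(sample_id, group="case", sex="male", assay="ES", **kw):
    return SampleRecord(
        sample_id=sample_id, sex=sex, group=group, assay=assay, **kw
    )


def make_variant(sample_id, gene="GENE1", **kw):
    defaults = dict(
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        genotype="het",
        consequence="stop_gained",
        impact="high",
        cadd=None,
        maf=None,
        quality_pass=True,
    )
    defaults.update(kw)
    return SmallVariant(sample_id=sample_id, gene=gene, **defaults)


@pytest.fixture
def tiny_cohort():
    """4 cases, 6 controls; GENE1 enriched in cases."""
    samples = [make_sample(f"case{i}", "case") for i in range(4)] + [
        make_sample(f"ctrl{i}", "control") for i in range(6)
    ]
    variants = [
        make_variant("case0"),
        make_variant("case1"),
        make_variant("ctrl0", maf=0.0005),
    ]
    return samples, variants
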