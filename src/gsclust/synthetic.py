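"""Synthetic gene-set collections and reference fixture files.

The planted-partition generator draws gene-sets around disjoint
group-specific gene pools plus a shared background pool: a set in group g
samples ``round(within_overlap * set_size)`` genes from pool g and the rest
from the background, without replacement within the set.  Sets in the same
group therefore share pool genes (high within-group similarity) while sets
from different groups can only overlap by chance through the background.
Ground-truth labels are returned so cluster-recovery can be scored (e.g. by
the adjusted Rand index).

:func:`write_fixture_files` emits small reference files in every input
dialect the readers support (IPA export, GREAT export, GMT, mapping TSV,
highlight subset, annotation GMT); these files *define* the dialects the
parsers target.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .model import GeneSetCollection, SourceTool, create_collection


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-partition generator.

    Defaults are the well-separated study condition used throughout the test
    suite: 3 groups of 8 sets, 20 genes per set of which 90% come from the
    group's private 40-gene pool and the rest from a 200-gene shared
    background.
    """

    n_groups: int = 3
    sets_per_group: int = 8
    pool_size: int = 40
    set_size: int = 20
    within_overlap: float = 0.9
    background_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_overlap <= 1.0):
            raise ValueError("within_overlap must lie in (0, 1]")
        if self.n_own > self.pool_size or self.noise_genes > self.background_size:
            raise ValueError("infeasible draw sizes for the given pools")
        if self.set_size > self.pool_size + self.background_size:
            raise ValueError("set_size exceeds total available genes")

    @property
    def n_own(self) -> int:
        """Genes drawn from the group's own pool."""
        return round(self.within_overlap * self.set_size)

    @property
    def noise_genes(self) -> int:
        """Genes drawn from the shared background pool."""
        return self.set_size - self.n_own


def generate_planted_collection(
    design: PlantedDesign,
) -> tuple[GeneSetCollection, tuple[int, ...]]:
    """Draw a collection with planted group structure; returns the collection
    and the ground-truth group label (1-based) of every set."""
    rng = np.random.default_rng(design.seed)
    pools = [
        [f"G{g + 1}_{i:03d}" for i in range(design.pool_size)]
        for g in range(design.n_groups)
    ]
    background = [f"BG{i:03d}" for i in range(design.background_size)]

    records = []
    labels: list[int] = []
    for g in range(design.n_groups):
        for s in range(design.sets_per_group):
            own = rng.choice(pools[g], size=design.n_own, replace=False)
            noise = (
                rng.choice(background, size=design.noise_genes, replace=False)
                if design.noise_genes
                else np.array([], dtype=object)
            )
            genes = [str(x) for x in own] + [str(x) for x in noise]
            records.append(
                dict(
                    name=f"Set_g{g + 1}_s{s + 1}",
                    genes=genes,
                    experiment="synthetic",
                    source_tool=SourceTool.GENERIC,
                    species="HUMAN",
                )
            )
            labels.append(g + 1)
    return create_collection(records), tuple(labels)


def expected_between_group_jaccard(design: PlantedDesign) -> float:
    """Exact expectation of the Jaccard index between two sets from
    *different* groups: with disjoint pools, overlap comes only from the
    background draws, so C ~ Hypergeometric(background_size, noise, noise)
    and E[J] = sum_c P(C=c) * c / (2*set_size - c)."""
    nb, B, s = design.noise_genes, design.background_size, design.set_size
    cs = np.arange(0, nb + 1)
    pmf = hypergeom.pmf(cs, B, nb, nb)
    return float(np.sum(pmf * cs / (2 * s - cs)))


# ---------------------------------------------------------------------------
# Reference fixture files (these define the parser dialects)
# ---------------------------------------------------------------------------

_IPA_FIXTURE = """\
© 2000-2020 QIAGEN. All rights reserved.
Ingenuity Canonical Pathways\t-log(p-value)\tRatio\tz-score\tMolecules
Oxidative Phosphorylation\t6.21\t0.18\t-2.3\tNDUFA1,NDUFB5,COX5A,ATP5F1,UQCRC2
Mitochondrial Dysfunction\t5.02\t0.15\t\tNDUFA1,COX5A,SOD2,CAT,GPX1
NRF2-mediated Oxidative Stress Response\t3.4\t0.11\t1.9\tSOD2,CAT,GPX1,NQO1,GCLC/GCLM
EIF2 Signaling\t2\t0.09\t-0.4\tEIF2S1,EIF4E,RPL5,RPS6
Sirtuin Signaling Pathway\t1.5\t0.08\t0.2\tSOD2,NDUFA1,ATP5F1,TP53
mTOR Signaling\t1.2\t0.07\t\tRPS6,EIF4E,AKT1,MTOR
"""

_GREAT_FIXTURE = """\
# GREAT version 4.0.4
# Species assembly: hg38
# Association rule: Basal+extension
Ontology\tTerm Name\tHyper FDR Q-Val\tGenes
GO Biological Process\tresponse to oxidative stress\t0.0001\tSOD2,CAT,GPX1,NQO1
GO Biological Process\tmitochondrial ATP synthesis\t0.003\tATP5F1,NDUFA1,UQCRC2
GO Molecular Function\tantioxidant activity\t0.01\tSOD2,CAT,GPX1
MSigDB Pathway\toxidative phosphorylation\t0.02\tNDUFA1,NDUFB5,COX5A,ATP5F1
"""

_GMT_FIXTURE = """\
RosPathwayMouse\tGO Biological Process\tSod2\tCat\tGpx1\tNqo1
MitoPathwayMouse\tGO Biological Process\tNdufa1\tCox5a\tAtp5f1
TrpPathwayMouse\tGO Molecular Function\tTrp53\tMdm2\tAkt1
"""

_MAPPING_FIXTURE = """\
source_id\tsource_namespace\tspecies\ttarget_symbol
Sod2\tSYMBOL\tmouse\tSOD2
Cat\tSYMBOL\tmouse\tCAT
Gpx1\tSYMBOL\tmouse\tGPX1
Nqo1\tSYMBOL\tmouse\tNQO1
Ndufa1\tSYMBOL\tmouse\tNDUFA1
Cox5a\tSYMBOL\tmouse\tCOX5A
Atp5f1\tSYMBOL\tmouse\tATP5F1
Trp53\tSYMBOL\tmouse\tTP53
Mdm2\tSYMBOL\tmouse\tMDM2
Akt1\tSYMBOL\tmouse\tAKT1
Mtor\tSYMBOL\tmouse\tMTOR
Ucp2\tSYMBOL\tmouse\tUCP2
"""

_HIGHLIGHT_FIXTURE = """\
SOD2
CAT
GPX1
NQO1
GCLC
GCLM
"""

_ANNOTATION_GMT_FIXTURE = """\
ROS_DEFENSE\toxidative stress defense\tSOD2\tCAT\tGPX1\tNQO1\tGCLC\tGCLM
OXPHOS\toxidative phosphorylation\tNDUFA1\tNDUFB5\tCOX5A\tATP5F1\tUQCRC2
TRANSLATION\tprotein synthesis\tEIF2S1\tEIF4E\tRPL5\tRPS6
P53_NETWORK\tp53 signalling\tTP53\tMDM2\tAKT1
"""


def write_fixture_files(out_dir: "str | Path") -> list[Path]:
    """Write the reference input fixtures: an IPA canonical-pathway export
    (banner + header + 6 rows), a GREAT all-ontologies export (2 ontologies),
    a mouse-symbol GMT fully covered by the bundled mouse-to-human mapping
    TSV, a highlight gene subset, and an annotation GMT for ORA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contents = {
        "ipa_export.tsv": _IPA_FIXTURE,
        "great_export.tsv": _GREAT_FIXTURE,
        "mouse_sets.gmt": _GMT_FIXTURE,
        "mouse_to_human.tsv": _MAPPING_FIXTURE,
        "highlight_genes.txt": _HIGHLIGHT_FIXTURE,
        "annotations.gmt": _ANNOTATION_GMT_FIXTURE,
    }
    paths = []
    for fname, text in contents.items():
        p = out_dir / fname
        p.write_text(text, encoding="utf-8")
        paths.append(p)
    return paths
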