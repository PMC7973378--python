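import numpy as np
import pandas as pd
import pytest

from promoscan.synthetic import SyntheticGenomeSpec, generate_genome
from promoscan.trends import ExpressionMatrix


@pytest.fixture(scope="session")
def toy_genome():
    """Small deterministic genome: 3 contigs x 8 genes, promoter-safe spacing."""
    spec = SyntheticGenomeSpec(n_contigs=3, genes_per_contig=8, intergenic_len=1200,
                               gene_len=400, gc_fraction=0.4, seed=11)
    contigs, genes = generate_genome(spec)
    return spec, contigs, genes


def make_matrix(cell_means: dict[str, np.ndarray], gene_ids, n_replicates: int = 1,
                noise: float = 0.0, seed: int = 0) -> ExpressionMatrix:
    """Expression matrix with exact per-(genotype, treatment) cell means.

    ``cell_means`` maps "genotype_treatment" -> per-gene mean vector.
    """
    rng = np.random.default_rng(seed)
    cols, design_rows = {}, []
    for key, mu in cell_means.items():
        geno, treat = key.split("_")
        for r in range(1, n_replicates + 1):
            name = f"{geno}_{treat}_rep{r}"
            vals = np.asarray(mu, dtype=float)
            if noise:
                vals = vals * np.exp(rng.normal(0, noise, size=len(vals)))
            cols[name] = vals
            design_rows.append((name, geno, treat, r))
    values = pd.DataFrame(cols, index=list(gene_ids))
    design = pd.DataFrame(design_rows, columns=["sample", "genotype", "treatment", "replicate"])
    return ExpressionMatrix(values, design)
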