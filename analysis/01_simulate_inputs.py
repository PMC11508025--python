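"""Generate every input the analysis needs: the toy base network, its three
phenotype variants, the growth medium, and a clustered expression matrix.

Writes models (SBML + JSON), the medium CSV, and the counts matrix (sparse
MTX with gene/cell annotation TSVs) under results/inputs/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from spheroflux import (
    SyntheticExpressionConfig,
    ToyNetworkConfig,
    make_expression_matrix,
    make_medium,
    make_phenotype_variants,
    make_toy_base_model,
    validate_model,
    write_model,
)

warnings.filterwarnings("ignore")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results/inputs")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    base = make_toy_base_model(ToyNetworkConfig(seed=args.seed))
    medium = make_medium("l15_like")
    write_model(base, outdir / "toy_base.xml", format="sbml")
    write_model(base, outdir / "toy_base.json", format="json")
    medium.to_csv(outdir / "medium_l15_like.csv")

    report = validate_model(base, medium)
    print(
        f"toy base network: {len(base.reactions)} reactions, "
        f"{len(base.metabolites)} metabolites, {len(base.genes)} genes"
    )
    print(
        f"  mass-balanced fraction {report.mass_balanced_fraction:.2f}, "
        f"biomass producible: {report.biomass_producible}, "
        f"blocked: {report.blocked_reaction_ids}"
    )

    for name, model in make_phenotype_variants(base).items():
        write_model(model, outdir / f"variant_{name}.json", format="json")
    print("phenotype variants written: proliferative (Warburg-capped), "
          "invasive (lactate consumer), reservoir (fumarate/ATP exporter)")

    matrix, labels = make_expression_matrix(
        base, SyntheticExpressionConfig(seed=args.seed)
    )
    scipy.io.mmwrite(
        outdir / "counts.mtx", scipy.sparse.csr_matrix(matrix.to_numpy())
    )
    pd.Series(matrix.columns, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    labels.rename_axis("cell").to_csv(outdir / "cells.tsv", sep="\t")
    matrix.to_csv(outdir / "counts_dense.csv")
    print(
        f"expression matrix: {matrix.shape[0]} cells x {matrix.shape[1]} "
        f"genes across clusters {sorted(labels.unique())}"
    )


if __name__ == "__main__":
    main()
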