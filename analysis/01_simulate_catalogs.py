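#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes, under results/data/:

* a catalog of 12 metabolite-like exposure GWAS (2 with a planted effect
  theta = 0.25 on the outcome) and 6 immune-trait-like mediator GWAS
  (2 planted), each with 30 instruments, against one shared outcome GWAS;
* one exposure -> mediator -> outcome triple with a planted causal chain
  (theta_xm = 0.3, theta_my = 0.2, direct = 0.4, so the true mediated
  proportion is 13.04%), plus its block-LD matrix.

All tables use the GWAS-SSF-style dialect the reader consumes, so the
downstream scripts exercise the same I/O path as real summary statistics.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from mrmediate.io import write_manifest, write_summary_stats
from mrmediate.simulate import SimConfig, catalog, simulate_ld, simulate_mediation_triple

SEED = 2025
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(m_snps=30, seed=SEED)
    exposures, outcome1 = catalog(cfg, n_traits=12, n_causal=2, theta=0.25,
                                  trait_class="metabolite", prefix="E")
    mcfg = dataclasses.replace(cfg, seed=SEED + 1)
    mediators, outcome2 = catalog(mcfg, n_traits=6, n_causal=2, theta=0.25,
                                  trait_class="immune", prefix="M")
    outcome = outcome1
    outcome.df = pd.concat([outcome1.df, outcome2.df], ignore_index=True)

    rows = []
    for t in exposures + mediators:
        path = write_summary_stats(t, OUT / f"{t.trait_id}.tsv")
        rows.append({"path": path.name, "trait_id": t.trait_id,
                     "trait_class": t.trait_class})
    pd.DataFrame(rows).to_csv(OUT / "catalog_manifest.tsv", sep="\t",
                              index=False)
    write_summary_stats(outcome, OUT / "outcome.tsv")

    tcfg = SimConfig(theta_xm=0.3, theta_my=0.2, direct_xy=0.4,
                     seed=SEED + 2)
    exp, med, out, truth = simulate_mediation_triple(tcfg)
    for t, name in ((exp, "triple_exposure"), (med, "triple_mediator"),
                    (out, "triple_outcome")):
        write_summary_stats(t, OUT / f"{name}.tsv")
    ld = simulate_ld(tcfg, list(exp.df["snp_id"]))
    pd.DataFrame(ld.r2, columns=ld.snp_ids).to_csv(
        OUT / "triple_ld.tsv", sep="\t", index=False)
    (OUT / "triple_truth.json").write_text(json.dumps(
        {k: v for k, v in truth.items()
         if isinstance(v, (int, float, str))}, indent=2))

    write_manifest(OUT, {"seed": SEED, "catalog_m_snps": 30,
                         "planted_theta": 0.25,
                         "triple": dataclasses.asdict(tcfg)}, SEED)
    print(f"wrote {len(exposures)} exposures, {len(mediators)} mediators, "
          f"1 outcome ({outcome.n_snp} SNPs) and a planted mediation triple "
          f"(true mediated proportion {truth['proportion_pct']:.3f}%) "
          f"to {OUT}")


if __name__ == "__main__":
    main()
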