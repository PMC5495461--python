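#!/usr/bin/env python
"""Generate the synthetic study: four pooled small-RNA libraries (CK and
Stages I-III), a random genome with gene models, planted siRNA duplex loci,
siRNA-gene cleavage links, 24-nt siRNA methylation links, and decoys.

Writes the input bundle to results/sim/ and prints what was planted.
"""

from pathlib import Path

from sirna_callus.simulate import SimulationConfig, simulate_all, write_bundle

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    config = SimulationConfig(seed=SEED)
    bundle = simulate_all(config)
    write_bundle(bundle, OUT)
    truth = bundle.truth
    n_duplex = len(truth.loci_by_kind("duplex"))
    n_near = len(truth.loci_by_kind("near_miss"))
    n_decoy = len(truth.loci_by_kind("decoy_single"))
    n_de = sum(1 for p in truth.planted_loci if p.is_de and p.kind == "duplex")
    print(f"wrote synthetic study to {OUT}")
    print(f"genome: {config.genome_length} bp, {len(bundle.genes)} genes, "
          f"{len(bundle.excluded)} excluded-class intervals")
    print(f"planted: {n_duplex} duplex loci ({n_de} with fold changes), "
          f"{n_near} near-miss pairs, {n_decoy} single-strand decoys")
    print(f"links: {len(truth.cleavage_links)} cleavage, "
          f"{len(truth.methyl_links)} 24-nt methylation")
    print(f"tag table: {len(bundle.tag_table)} tags across 4 libraries")


if __name__ == "__main__":
    main()
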