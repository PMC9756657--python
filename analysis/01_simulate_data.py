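#!/usr/bin/env python
"""Generate the ground-truthed synthetic study data every later step uses.

Emits, under scratch/synthetic/ (bulky) and results/ (small summaries):
  - focal / donorA / donorB genomes (FASTA) with planted donorB blocks
  - HiFi-like reads (FASTA) and their alignments to all three references (PAF)
  - coalescent genotypes for 5 populations (VCF) with truth block BED
  - probe hits + genetic map TSVs for the anchoring stage
  - truth.json with block coordinates, chimera joins and scaffold order
"""

import json
from pathlib import Path

import pandas as pd

from intropipe.io_formats import write_bed, write_fasta, write_paf, write_vcf
from intropipe.synthetic_data import (
    SimulationParams,
    simulate_alignments,
    simulate_genomes,
    simulate_genotypes,
    simulate_probe_map,
    simulate_reads,
)

SEED = 42
SCRATCH = Path("scratch/synthetic")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    params = SimulationParams(seed=SEED)

    focal, donorA, donorB, truth = simulate_genomes(params)
    write_fasta(focal, SCRATCH / "focal.fa")
    write_fasta(donorA, SCRATCH / "donorA.fa")
    write_fasta(donorB, SCRATCH / "donorB.fa")
    write_bed(truth.introgressed_blocks, RESULTS / "truth_blocks.bed")

    reads = simulate_reads(focal, params)
    write_fasta(reads, SCRATCH / "reads.fa")
    records = simulate_alignments(reads, focal, donorA, donorB, truth)
    for label in ("focal", "donorA", "donorB"):
        write_paf([r for r in records if r.ref_label == label],
                  SCRATCH / f"aln_{label}.paf")

    genotypes, geno_truth = simulate_genotypes(params)
    write_vcf(genotypes, SCRATCH / "genotypes.vcf")
    write_bed(geno_truth.introgressed_blocks, RESULTS / "truth_genotype_blocks.bed")
    pd.DataFrame(
        {"sample": genotypes.samples,
         "population": [genotypes.populations[s] for s in genotypes.samples]}
    ).to_csv(SCRATCH / "populations.tsv", sep="\t", index=False)

    hits, gmap, scaffolds, map_truth = simulate_probe_map(params)
    hits.to_csv(SCRATCH / "probe_hits.tsv", sep="\t", index=False)
    gmap.to_csv(SCRATCH / "genetic_map.tsv", sep="\t", index=False)
    write_fasta(scaffolds, SCRATCH / "map_scaffolds.fa")

    with open(RESULTS / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": SEED,
                "genome_length": params.genome_length,
                "admixture_proportion": params.admixture_proportion,
                "introgressed_blocks": [
                    {"seqid": b.seqid, "start": b.start, "end": b.end}
                    for b in truth.introgressed_blocks
                ],
                "genotype_blocks": [
                    {"seqid": b.seqid, "start": b.start, "end": b.end}
                    for b in geno_truth.introgressed_blocks
                ],
                "chimera_joins": map_truth.chimera_joins,
            },
            fh,
            indent=1,
        )

    total_block = sum(b.length for b in truth.introgressed_blocks)
    print(f"genomes: {params.n_scaffolds} scaffolds, {params.genome_length} bp; "
          f"{len(truth.introgressed_blocks)} planted blocks totalling {total_block} bp "
          f"({total_block / params.genome_length:.1%} of the genome)")
    print(f"reads: {len(reads)} ({reads.total_length() / params.genome_length:.1f}x)")
    print(f"genotypes: {genotypes.n_sites} sites x {len(genotypes.samples)} samples")
    print(f"map fixture: {len(scaffolds)} scaffolds, "
          f"{len(map_truth.chimera_joins)} injected chimeras")


if __name__ == "__main__":
    main()
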