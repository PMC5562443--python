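"""CpG methylation from clone panels and a genome-scale count table.

Simulates a bisulfite clone panel over two promoter regions (one gaining
methylation, one refractory) and a whole-chromosome CpG count table with
hypomethylated promoters, then quantifies region, promoter-average and
genome-tile methylation.
"""

from exitscape.methylation import genome_average, promoter_average, region_percent
from exitscape.synthetic import SimulationConfig, simulate_clone_panel, simulate_genome

config = SimulationConfig(seed=2)

clones = simulate_clone_panel(config)
for name, positions in clones.regions.items():
    pct = region_percent(clones.panel, positions)
    print(f"clone panel {name}: {pct:.1f}% methylated "
          f"(planted probability {100 * clones.truth[name]:.0f}%)")

genome = simulate_genome(config)
prom = promoter_average(genome.cpg_table, genome.genes, upstream=2000,
                        chrom_sizes=genome.chrom_sizes)
tiles = genome_average(genome.cpg_table, genome.chrom_sizes, tile=50_000)
print(f"promoter average (2 kb upstream windows): {prom.percent:.1f}% "
      f"over {prom.n_windows} promoters")
print(f"genome average (50 kb tiles): {tiles.percent:.1f}% over {tiles.n_windows} tiles")
print("Promoters sit well below the genome-wide level, the hypomethylated-"
      "promoter landscape the generator plants; window percentages pool "
      "methylated/total read counts over the CpGs of each window.")
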