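"""Distance-shell filtering and interaction count tables.

Extracts pairs from a mixed synthetic population, tallies them into the
(central x neighbor-type) count table, and splits Asp carboxylate
oxygens into the two inner distance shells used for close-contact
rendering (<= 3.5 A) versus the broader contact band (3.5 - 4.5 A].
"""

from polarframe import (
    ARG_FRAME,
    AxialCap,
    EquatorialBand,
    PopulationSpec,
    count_interactions,
    count_table_to_tsv,
    extract_pairs,
    generate_population,
    shell_filter,
)

spec = PopulationSpec(
    n_pairs=200,
    components=(
        AxialCap(weight=0.5, neighbor_type="LEU"),
        EquatorialBand(weight=0.5, neighbor_type="ASP"),
    ),
    r_range=(3.0, 4.5),
    seed=33,
)
result = generate_population(spec)

pairs = []
for planted in result.pairs:
    pairs.extend(extract_pairs(planted.residues, ARG_FRAME, cutoff=5.0))

table = count_interactions(pairs)
print(count_table_to_tsv(table.loc[:, ["ASP", "LEU"]]))

inner = outer = 0
for pair in pairs:
    if pair.neighbor.res_type != "ASP":
        continue
    inner += len(shell_filter(pair, "carboxylate-O", 0.0, 3.5))
    outer += len(shell_filter(pair, "carboxylate-O", 3.5, 4.5))
print(f"Asp carboxylate oxygens: {inner} within 3.5 A, "
      f"{outer} in the (3.5, 4.5] A shell")

# Counts match the generator's ledger composition exactly; the shell
# split shows how the per-figure cutoffs (3.5/3.75/4.0/4.5 A) carve the
# same pair set into non-overlapping distance classes.
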