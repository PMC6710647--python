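"""Build the preset repeated-gene locus and apply a deletion-forming NAHR
event between its two outermost same-orientation family copies.

Prints the locus inventory, the event's exactly-known deleted interval, and
verifies that the sequence length is conserved: parent = mutant + deletion.
"""

import locuskit as lk

locus = lk.build_locus(lk.i_i_allele_config(seed=7))
members = locus.family_members()
unique = [f for f in locus.features if f.family == "unique"]
print(f"locus: {locus.genome_length:,} bp, {len(members)} family copies, "
      f"{len(unique)} unique genes")

mutant, event = lk.apply_nahr(locus, donor="CHS5", acceptor="CHS1", junction=600)
s, e = event.deleted_interval
print(f"NAHR {event.donor_gene_id} -> {event.acceptor_gene_id} "
      f"(junction after template base {event.crossover_junction}):")
print(f"  deleted interval [{s:,}, {e:,}] = {event.deletion_length:,} bp")
print(f"  surviving family copies: "
      f"{[f.gene_id for f in mutant.family_members()]}")
print(f"  length conserved: "
      f"{mutant.genome_length:,} + {event.deletion_length:,} "
      f"= {mutant.genome_length + event.deletion_length:,} bp")
# The deletion length equals the ATG-to-ATG distance of the two copies,
# independent of where inside the gene the template switch happened.
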