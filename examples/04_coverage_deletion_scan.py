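"""Detect an NAHR deletion from a normalized resequencing coverage track.

Simulates mutant-vs-reference coverage under the multimap allocation model
(unique sequence in the deletion drops to zero; family copies dim to the
surviving/original ratio), then calls the deletion from runs of near-zero
unique genes and compares the call with the planted truth.
"""

import locuskit as lk

locus = lk.build_locus(lk.i_i_allele_config(seed=7))
mutant, event = lk.apply_nahr(locus, "CHS5", "CHS1", junction=600)
track = lk.simulate_coverage(
    locus, mutant, lk.CoverageSimConfig(mean_depth=30.0, seed=8)
)

chs = locus.feature("CHS3b")
sub = locus.feature("subtilisin")
print(f"depth at a surviving unique gene: {track.slice_mean(sub.start, sub.end):.1f}")
print(f"depth at a family copy (1 of 12 surviving): "
      f"{track.slice_mean(chs.start, chs.end):.1f}  (~30/12 = 2.5)")

(call,) = lk.call_deletion(track, locus.features)
s, e = event.deleted_interval
cs, ce = call.interval
inter = max(0, min(e, ce) - max(s, cs) + 1)
print(f"called deletion [{cs:,}, {ce:,}] ({call.confidence}), "
      f"supported by {call.supporting_unique_genes}")
print(f"planted deletion [{s:,}, {e:,}]; reciprocal overlap "
      f"{min(inter / (e - s + 1), inter / (ce - cs + 1)):.3f}")
# The call is anchored on the eight unique genes inside the deletion; its
# edges extend to the midpoints toward the flanking expressed unique genes.
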