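"""Resolve the deletion breakpoint to the base pair from short reads.

Plants a 662,463-bp deletion with 2-bp junction microhomology and a 1-bp
untemplated 'C' insertion in a 3-Mb synthetic reference, simulates 91-bp
paired-end reads at 20x from a heterozygous carrier, aligns them with the
built-in seed-and-extend aligner, and calls the deletion from depth,
discordant pairs and split reads.
"""

from lethalmap import svreads

dele = svreads.PlantedDeletion(proximal_end=20_100_649, length=662_463,
                               microhomology=2, insertion="C")
ref = svreads.make_reference(length=3_000_000, deletion=dele,
                             origin=18_700_000, seed=7)
carrier = svreads.build_carrier_allele(ref, dele)
reads = svreads.simulate_reads([("wt", ref.codes, 0.5),
                                ("carrier", carrier, 0.5)],
                               coverage=20.0, seed=11)
aln = svreads.align_reads(reads, ref)
call = svreads.call_deletion_sv(aln, ref)

print(f"simulated {reads.n_pairs:,} read pairs "
      f"({aln.table['aligned'].mean():.1%} aligned)")
print(f"called deletion size: {call.size:,} bp "
      f"(planted {dele.length:,} bp)")
print(f"junction: last retained base {call.proximal_end:,}, "
      f"first distal base {call.distal_start:,}")
print(f"microhomology: {call.microhomology} bp, "
      f"untemplated insertion: '{call.insertion}'")
print(f"support: {call.n_split_reads} split reads, "
      f"{call.n_discordant_pairs} discordant pairs; "
      f"depth ratio in deletion {call.depth_ratio:.2f} (expected 0.5 for a "
      "heterozygote)")
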