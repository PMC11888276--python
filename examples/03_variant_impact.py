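"""Saturation mutagenesis and deltaSVM variant scoring of one region.

Trains a toy model, extracts its complete k-mer weight table, saturates a
motif-bearing region with every possible SNV and prints where the most
damaging variants fall.  VIP scores are differences of additive k-mer weight
sums (deltaSVM); strongly negative positions mark bases the model relies on
— they should coincide with the planted motif.
"""

import random

import numpy as np

from crevip import (GkmParams, extract_kmer_weights, train_model,
                    saturation_mutagenesis, summed_vip_track)
from crevip.io import GenomicRegion

rng = random.Random(1)
rand = lambda n: "".join(rng.choice("ACGT") for _ in range(n))

MOTIF = "GATTACA"
positives = [rand(12) + MOTIF + rand(12) for _ in range(30)]
negatives = [rand(31) for _ in range(30)]
model = train_model(positives, negatives, GkmParams(word_length=5, k=3),
                    seed=0, class_label="toy")
table = extract_kmer_weights(model)

region_seq = rand(20) + MOTIF + rand(20)
region = GenomicRegion("chr1", 1000, 1000 + len(region_seq), name="example")
vip = saturation_mutagenesis(table, region, sequence=region_seq)
track = summed_vip_track(vip)

print(f"saturation entries: {vip.n_entries} (= 3 x {len(region_seq)} positions)")
worst = min(track, key=track.get)
print(f"most damaging position: {worst[1]} (region-relative "
      f"{worst[1] - region.start}), summed VIP {track[worst]:+.3f}")
print(f"planted motif occupies region-relative positions 20..26")
per_pos = np.array([track[(region.chrom, region.start + p)]
                    for p in range(len(region_seq))])
print("mean summed VIP inside motif :", per_pos[20:27].mean().round(3))
print("mean summed VIP outside motif:",
      np.r_[per_pos[:20], per_pos[27:]].mean().round(3))
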