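"""Curate pool-search PSMs into ground truth and split without leakage.

Pool-based synthetic peptide searches are filtered (top PSM per spectrum,
PEP < 0.01, expected-in-pool including N-terminal truncations, score >= 70)
and the resulting peptides are split 80/10/10 so that no peptide in one
partition is a substring of a peptide in another.
"""

from timsrescore import (
    PSM,
    curate_psms,
    generate_pools,
    leakfree_split,
)
from timsrescore.synthetic import random_peptides

pools, planted = generate_pools(2, 50, seed=9, truncation_rate=0.2)
pool_map = {p.pool_id: p for p in pools}

# simulate search output: expected peptides, planted truncations, and junk
psms = []
i = 0
for pool in pools:
    for seq in sorted(pool.expected_peptides):
        psms.append(PSM(psm_id=f"p{i}", spectrum_id=f"s{i}", sequence=seq,
                        modifications={}, precursor_charge=2,
                        search_score=60.0 + (i % 60), pep=0.001 * (1 + i % 15),
                        is_decoy=False, pool_id=pool.pool_id))
        i += 1
    for seq in planted[pool.pool_id]:
        psms.append(PSM(psm_id=f"p{i}", spectrum_id=f"s{i}", sequence=seq,
                        modifications={}, precursor_charge=2, search_score=95.0,
                        pep=0.002, is_decoy=False, pool_id=pool.pool_id))
        i += 1

curated = curate_psms(psms, pool_map)
print(f"{len(psms)} search PSMs -> {len(curated)} ground-truth PSMs "
      "(top-per-spectrum, PEP < 0.01, expected-in-pool, score >= 70)")

peptides = sorted({p.sequence for p in curated}) + random_peptides(
    2000, seed=9, substring_rate=0.05
)
split = leakfree_split(peptides, fractions=(0.8, 0.1, 0.1), seed=9)
fractions = split.realized_fractions()
print(f"split {len(split.assignment)} peptides into "
      + ", ".join(f"{name} {fractions[name]:.1%}" for name in
                  ("train", "validation", "test"))
      + f" across {split.n_groups} containment groups")
print("co-containing peptides always share a partition, so no fragment "
      "ladder seen in training can reappear at evaluation time")
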