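"""Build the two similarity inputs from their native file formats.

Chemical similarity comes from fingerprint bit vectors via the Tanimoto
coefficient (values below 0.5 are suppressed as noise); protein similarity
comes from sequence-search bit scores via the self-normalized ratio
d_bit(p1,p2)/d_bit(p1,p1), symmetrized over the two query directions.
"""

import tempfile
from pathlib import Path

from dtocf import (
    build_chemical_similarity,
    build_protein_similarity,
    read_blast_tabular,
    read_fingerprints,
    self_bit_scores,
)

workdir = Path(tempfile.mkdtemp())

# --- chemical side: id, fingerprint length, hex-encoded bit vector
fp_file = workdir / "fingerprints.tsv"
fp_file.write_text(
    "aspirin\t16\tF0F0\n"      # bits {0-3, 8-11}
    "salicylate\t16\tF0B0\n"   # bits {0-3, 8, 10, 11} -> Tanimoto 6/8
    "caffeine\t16\t000F\n"     # bits {12-15}, disjoint from both
)
fps = read_fingerprints(fp_file)
C = build_chemical_similarity(fps, noise_threshold=0.5)
print("chemical similarity (Tanimoto, <0.5 zeroed as noise):")
for i, j, value in C.nonzero_pairs():
    print(f"  {fps.vocabulary.ids[i]} - {fps.vocabulary.ids[j]}: {value:.3f}")
print("  caffeine shares no substructure bits, so it has no edges\n")

# --- protein side: standard 12-column tabular sequence-search hits
blast_file = workdir / "hits.tsv"
rows = [
    ("KINASE1", "KINASE1", "100", "300", "0", "0", "1", "300", "1", "300", "1e-180", "600"),
    ("KINASE2", "KINASE2", "100", "280", "0", "0", "1", "280", "1", "280", "1e-170", "560"),
    ("KINASE1", "KINASE2", "45", "250", "120", "4", "5", "255", "3", "250", "1e-40", "180"),
    ("KINASE2", "KINASE1", "45", "250", "120", "4", "3", "250", "5", "255", "1e-40", "180"),
    ("KINASE1", "GPCR7", "22", "80", "60", "2", "10", "90", "200", "280", "0.5", "30"),
]
blast_file.write_text("\n".join("\t".join(r) for r in rows) + "\n")
hits = read_blast_tabular(blast_file, evalue_threshold=1e-5)
T = build_protein_similarity(hits, self_bit_scores(hits))
print("protein similarity (bit-score ratio, e-value <= 1e-5):")
for i, j, value in T.nonzero_pairs():
    print(f"  {T.vocabulary.ids[i]} - {T.vocabulary.ids[j]}: {value:.3f}")
print("  the weak GPCR7 hit (e-value 0.5) was filtered out; the kinase pair "
      "averages 180/600 and 180/560 over the two query directions")
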