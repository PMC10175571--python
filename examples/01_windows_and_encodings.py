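"""Extract serine-centered windows from a protein and encode them.

Builds a small protein in memory, pulls the 41-mer window around each serine
(padding with '_' at the termini), and prints the dimensional contract of each
of the five encodings.
"""

from psadpr import ProteinRecord, encode, extract_window

protein = ProteinRecord("DEMO1", "MKSAAAKRKT" + "A" * 35 + "S" + "A" * 35 + "GRKS")

windows = [
    extract_window(protein, i)
    for i, ch in enumerate(protein.sequence, start=1)
    if ch == "S"
]
print(f"{protein.id}: {len(protein)} residues, {len(windows)} serines")
for w in windows:
    print(f"  position {w.source_position:>3}  {w.peptide}")

print("\nencoding shape contracts (n_windows, positions, channels):")
for name in ("OH", "ZSCALE", "WE", "EAAC", "EGAAC"):
    X = encode(windows, name)
    print(f"  {name:<7} {X.shape}   flat length per window: {X[0].size}")

# The first window sits at the N-terminus, so its left flank is padding and
# its one-hot rows there light up the 21st ('_') channel.
X = encode(windows, "OH")
print("\npad channel hits in window 1, left flank:", int(X[0, :20, 20].sum()))
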