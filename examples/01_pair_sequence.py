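"""From a PPR protein to its (6, 1') pair sequence.

Builds a toy PLS protein from an explicit motif table and extracts the
ordered (position-6, position-1') amino-acid pairs that the alignment model
consumes.  Each pair is typed by the repeat contributing position 6.
"""

from pprbind import PPRProtein, annotate_motifs, extract_pair_sequence

# Three contiguous repeats: P (35 aa), L (36 aa), S (31 aa).  Position 6 of
# each repeat and position 1 of the following repeat carry the coding
# residues; everything else is filler.
residues = list("A" * 102)
residues[5] = "T"    # position 6 of repeat 1 (P)
residues[35] = "D"   # position 1 of repeat 2  -> pair 1 = (T, D)
residues[40] = "N"   # position 6 of repeat 2 (L)
residues[71] = "N"   # position 1 of repeat 3  -> pair 2 = (N, N)
residues = "".join(residues)

motifs = annotate_motifs(residues, provided=[(1, 35), (36, 71), (72, 102)])
protein = PPRProtein(id="toy", residues=residues, motifs=motifs)
pairs = extract_pair_sequence(protein)

print(f"{protein.n_motifs} motifs ->  {pairs.m} pairs")
for t, tr in enumerate(pairs, start=1):
    print(f"  pair {t}: ({tr.aa6}, {tr.aa1p})  {tr.motif_type}-type")
# A protein with l motifs always yields l - 1 pairs; (T, D) in a P repeat
# prefers guanine under the recognition code, (N, N) in an L repeat is
# uncoded (the N-N rule applies to P/S repeats only).
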