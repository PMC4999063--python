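"""Anchored prediction at a known C-to-U edit site.

PLS-class editing factors bind so their terminal S-type repeat contacts the
nucleotide four bases upstream of the edited cytidine.  Given a known edit
position, sampling the upstream window and aligning candidate proteins to
it turns binding prediction into editing-factor assignment.
"""

import numpy as np

from pprbind import edit_site_window, train_model, viterbi_topw
from pprbind.motifs import RNATranscript
from pprbind.synthetic import (
    gen_cognate_site,
    gen_pair_sequence,
    gen_training_corpus,
    gen_transcript,
)

rng = np.random.default_rng(23)
model = train_model(gen_training_corpus(rng, n_events=100))

# Build a transcript whose edit site at position 120 has the query's
# cognate site ending exactly 4 bases upstream.
pairs = gen_pair_sequence(rng, m=10, frac_specific=1.0, protein_id="factor")
site = gen_cognate_site(pairs, rng)
backbone = gen_transcript(rng, 200, "target").bases
edit_pos = 120
site_end = edit_pos - 4  # last contacted base
bases = backbone[: site_end - len(site)] + site + backbone[site_end:]
transcript = RNATranscript(id="target", bases=bases)

window = edit_site_window(transcript, edit_pos=edit_pos, window_len=30)
print(f"window [{window.start},{window.end}] of length {len(window.bases)}")

hit = viterbi_topw(model, pairs, RNATranscript(id="win", bases=window.bases), w=1)[0]
last_contact = window.to_transcript(hit.span[1])
print(f"best alignment spans window positions {hit.span[0]}-{hit.span[1]} "
      f"(transcript {window.to_transcript(hit.span[0])}-{last_contact})")
print(f"anchored 4 bases upstream of the edit site: {window.is_anchored(last_contact)}")
# An anchored alignment with a strong score is the signature used to
# nominate a protein as the editing factor for a known edit position.
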