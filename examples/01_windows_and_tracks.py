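"""Cut a chain into windows and encode the five property tracks.

Each residue becomes the center of one odd-length window; chain ends are
padded with the dummy 'X'.  Every window carries five parallel symbol
strings: amino acid, polarization charge (p/n/u), hydropathy class (1-6),
secondary structure (H/E/C) and exposed/buried solvent accessibility.
"""

import numpy as np

import ionbind as ib

record = ib.ProteinRecord(
    chain_id="demo_A",
    sequence="MKDERLVASTG",
    binding={"SO4": np.array([0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=bool)},
    ss_track="CHHHHEECCCC",
    rsa_track=np.array([0.7, 0.5, 0.9, 0.8, 0.2, 0.1, 0.1, 0.3, 0.6, 0.5, 0.4]),
)

print(f"padded chain (L=7): {ib.pad_sequence(record.sequence, 7)}")
for seg in ib.extract_segments(record, "SO4", 7):
    marker = "+" if seg.positive else " "
    print(f"  pos {seg.center_index + 1:2d} {marker}  "
          f"aa={seg.window}  charge={seg.track_windows['charge']}  "
          f"ss={seg.track_windows['ss']}  rsa={seg.track_windows['rsa']}")
print("\n'+' marks windows centered on an annotated SO4-binding residue;")
print("'X' columns are terminal padding, mirrored on every track.")
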