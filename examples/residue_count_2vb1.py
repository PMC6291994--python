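"""Residue count of PDB entry 2vb1 (network-dependent integration check).

Downloads hen-egg lysozyme entry 2vb1 from the RCSB and counts its
C-alpha records: the expected count is 129 residues. Kept out of the
offline test suite because it needs network access.
"""

import urllib.request

from sriselect import read_calpha_cloud, residue_count

URL = "https://files.rcsb.org/download/2VB1.pdb"

with urllib.request.urlopen(URL, timeout=30) as fh:
    text = fh.read().decode()
cloud = read_calpha_cloud(text, source_label="2vb1")
n = residue_count(cloud)
print(f"2vb1 C-alpha count: {n} (expected 129)")
assert n == 129
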