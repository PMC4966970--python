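"""Check the deposited PiGV genome record (requires network access).

Downloads GenBank accession KX151395 from NCBI and verifies the two
headline sequence statistics: length 112,536 bp and 44.2% G+C.  This is
the only gvkit workflow that touches the network; everything else runs on
synthetic or shipped data.
"""

import sys
import urllib.request

from gvkit.genome import gc_content, round_half_away

ACCESSION = "KX151395"
URL = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
       f"?db=nuccore&id={ACCESSION}&rettype=fasta&retmode=text")

try:
    with urllib.request.urlopen(URL, timeout=30) as fh:
        lines = fh.read().decode().splitlines()
except OSError as exc:
    sys.exit(f"download failed ({exc}); this example needs network access")

seq = "".join(l.strip() for l in lines if not l.startswith(">")).upper()
print(f"{ACCESSION}: {len(seq)} bp (expected 112,536)")
print(f"G+C: {round_half_away(100 * gc_content(seq), 1)}% (expected 44.2%)")
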