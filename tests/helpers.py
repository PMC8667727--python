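"""Test-side access to the independent brute-force oracle.

The oracle itself lives in scripts/_oracle.py (shared with the
reproduction script); it is written with plain Python loops and scalar
vector algebra, independent of the package's vectorised code paths.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))

from _oracle import (brute_assign, brute_gamma, brute_theta,  # noqa: F401,E402
                     random_small_trace)
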