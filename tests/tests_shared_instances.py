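"""Tiny shared builders for abstract coefficient-space instances."""

import numpy as np

from fbcwf.basis import BasisSpec


def scalar_spec() -> BasisSpec:
    """A one-coefficient basis: single (n=0, k=1) entry."""
    return BasisSpec(L=8, bandlimit=10.0, ns=np.array([0]), ks=np.array([1]),
                     roots=np.array([2.4]), normalizers=np.array([1.0]))
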