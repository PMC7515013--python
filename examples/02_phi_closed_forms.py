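"""Phi_atomic on three hand-built systems with known closed forms.

Phi_atomic = sum_i H(X_t^(i) | X_{t+1}^(i)) - H(X_t | X_{t+1}) measures how
much information a system carries across one time step beyond the sum
carried by its nodes individually.
"""

from animatphi import (analytic_tpm, make_fixture, phi_atomic_eq3,
                       phi_atomic_from_tpm)

systems = {
    "copy  (each node keeps its own state)": "copy_brain",
    "swap  (the two nodes exchange states)": "swap_brain",
    "xor   (both next nodes equal x XOR y)": "xor_brain",
}

for label, name in systems.items():
    tpm = analytic_tpm(make_fixture(name))
    res = phi_atomic_from_tpm(tpm)       # conditional-entropy assembly
    cross = phi_atomic_eq3(tpm)          # mutual-information assembly
    print(f"{label}: Phi_atomic = {res.phi_atomic:.3f} bits "
          f"(cross-check {cross.phi_atomic:.3f})")

print("""
copy integrates nothing (0 bits): each part predicts itself perfectly.
swap integrates 2 bits: each node's past is invisible from its own future,
yet the whole map is invertible.  xor integrates 1 bit: the parity is held
jointly by the pair, never by one node alone.""")
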