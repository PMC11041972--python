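"""Independent reference implementations used as test oracles.

These deliberately mirror the operations with the dumbest possible
string splicing (quadratic time, character by character) so they share
no code path with the package.  They are only ever run on tiny inputs.
"""

from __future__ import annotations


def oracle_feistel_block(block: str, ek: str) -> str:
    """One Feistel round on a single 64-bit block, evaluated bit by bit."""
    assert len(block) == 64 and len(ek) == 32
    lt, rt = block[:32], block[32:]
    ar = "".join("1" if rt[j] == "1" and ek[j] == "1" else "0" for j in range(32))
    al = "".join("1" if ar[j] != lt[j] else "0" for j in range(32))
    return rt + al


def oracle_hide(cover: str, payload: str, fpk: int, dsk: int, fsk: int) -> str:
    """Insert payload characters one by one, as the pseudocode does."""
    assert len(payload) % fsk == 0
    fd = list(cover)
    i = fpk
    q = 0
    nseg = len(payload) // fsk
    for k in range(nseg):
        for _ in range(fsk):
            fd.insert(i, payload[q])
            q += 1
            i += 1
        if k < nseg - 1:
            i += dsk
    return "".join(fd)


def oracle_extract(
    stego: str, fpk: int, dsk: int, fsk: int, payload_len: int
) -> tuple[str, str]:
    """Read FSK-sized runs, skip DSK, character by character."""
    assert payload_len % fsk == 0
    payload = []
    taken = set()
    i = fpk
    nseg = payload_len // fsk
    for k in range(nseg):
        for _ in range(fsk):
            payload.append(stego[i])
            taken.add(i)
            i += 1
        if k < nseg - 1:
            i += dsk
    cover = "".join(c for j, c in enumerate(stego) if j not in taken)
    return "".join(payload), cover
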