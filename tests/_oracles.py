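"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the thinning oracle
applies the published two-subiteration deletion rules pixel by pixel
with plain Python loops.
"""

import numpy as np


def _neighbors(img, r, c):
    """P2..P9 clockwise from north; out-of-grid pixels are background."""

    def at(i, j):
        return img[i, j] if 0 <= i < img.shape[0] and 0 <= j < img.shape[1] else 0

    return [
        at(r - 1, c), at(r - 1, c + 1), at(r, c + 1), at(r + 1, c + 1),
        at(r + 1, c), at(r + 1, c - 1), at(r, c - 1), at(r - 1, c - 1),
    ]


def oracle_zhang_suen(mask):
    img = np.asarray(mask, dtype=np.uint8).copy()
    while True:
        deleted_any = False
        for pass_two in (False, True):
            to_delete = []
            for r in range(img.shape[0]):
                for c in range(img.shape[1]):
                    if not img[r, c]:
                        continue
                    p = _neighbors(img, r, c)
                    b = sum(p)
                    if not (2 <= b <= 6):
                        continue
                    a = sum(1 for i in range(8) if p[i] == 0 and p[(i + 1) % 8] == 1)
                    if a != 1:
                        continue
                    p2, p4, p6, p8 = p[0], p[2], p[4], p[6]
                    if not pass_two:
                        if p2 * p4 * p6 != 0 or p4 * p6 * p8 != 0:
                            continue
                    else:
                        if p2 * p4 * p8 != 0 or p2 * p6 * p8 != 0:
                            continue
                    to_delete.append((r, c))
            for r, c in to_delete:
                img[r, c] = 0
            deleted_any = deleted_any or bool(to_delete)
        if not deleted_any:
            return img.astype(bool)
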