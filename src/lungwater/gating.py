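"""Respiratory-phase selection.

Reconstructs the single analysis volume at the end-expiratory (functional
residual capacity, minimum lung volume) phase from the repeat series and the
navigator trace: repeats whose mean navigator displacement falls in the
end-expiration bin are averaged voxelwise.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .grids import NavigatorTrace, VoxelGrid


def repeat_mean_displacements(trace: NavigatorTrace, n_repeats: int) -> np.ndarray:
    """Mean navigator displacement of each repeat (one phase decision per
    complete acquisition)."""
    means = np.empty(n_repeats)
    for r in range(n_repeats):
        d = trace.samples_for(r)
        if d.size == 0:
            raise InputError(f"navigator trace has no samples for repeat {r}")
        means[r] = d.mean()
    return means


def select_frc_phase(
    repeats: list[VoxelGrid],
    trace: NavigatorTrace,
    frc_fraction: float = 0.3,
    invert: bool = False,
) -> VoxelGrid:
    """Average the repeats acquired nearest end-expiration.

    Parameters
    ----------
    repeats
        One signal volume per acquisition, identical geometry.
    trace
        Navigator trace covering every repeat. By convention larger
        displacement = more expired; pass ``invert=True`` for the opposite
        polarity.
    frc_fraction
        Repeats whose mean displacement lies within the ``frc_fraction`` of
        navigator samples nearest end-expiration are accepted. If no repeat
        qualifies, the single most-expired repeat is returned.
    """
    if not repeats:
        raise InputError("empty repeat list")
    if not 0 < frc_fraction <= 1:
        raise InputError("frc_fraction must be in (0, 1]")
    shape = repeats[0].shape
    spacing = repeats[0].spacing
    for rep in repeats[1:]:
        if rep.shape != shape or rep.spacing != spacing:
            raise InputError("repeats must share grid geometry")
    if trace.n_repeats < len(repeats):
        raise InputError(
            f"navigator trace covers {trace.n_repeats} repeats, "
            f"{len(repeats)} volumes given"
        )

    qualify = qualifying_repeats(trace, len(repeats), frc_fraction, invert)
    stack = np.stack([repeats[i].data for i in qualify])
    return repeats[0].with_data(stack.mean(axis=0))


def qualifying_repeats(
    trace: NavigatorTrace,
    n_repeats: int,
    frc_fraction: float = 0.3,
    invert: bool = False,
) -> np.ndarray:
    """Indices of the repeats assigned to the end-expiration bin.

    A repeat qualifies when its mean displacement lies at or beyond the
    ``1 − frc_fraction`` quantile of all navigator samples; if none does,
    the single most-expired repeat is returned.
    """
    disp = -trace.displacement if invert else trace.displacement
    trace_signed = NavigatorTrace(trace.times_ms, disp, trace.repeat_index)
    means = repeat_mean_displacements(trace_signed, n_repeats)
    threshold = np.quantile(disp, 1.0 - frc_fraction)
    qualify = np.flatnonzero(means >= threshold - 1e-12)
    if qualify.size == 0:
        qualify = np.array([int(np.argmax(means))])
    return qualify
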