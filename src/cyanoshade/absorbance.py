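"""Reduction of raw count triplets to relative absorbance.

A measurement consists of three count spectra on one grid: the sample
``n_m``, the source-off background ``n_b`` and the water-blank reference
``n_ref``.  The relative absorbance per bin is

    r = 1 - (n_m - n_b) / (n_ref - n_b) = 1 - I/I0 = 1 - exp(-tau)

Bins where the signal is not confidently above background are excluded via
the signal-to-noise ratio alpha = (n_m - n_b)/n_b with a cutoff of 3:
a bin is retained iff alpha >= cutoff.  Replicates (three distances, three
repeats each) are averaged bin-wise with a sample standard deviation.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .spectra import AbsorbanceSpectrum, CountSpectrum, check_common_grid

DEFAULT_SNR_CUTOFF = 3.0


def snr_mask(
    sample: CountSpectrum, background: CountSpectrum, cutoff: float = DEFAULT_SNR_CUTOFF
) -> np.ndarray:
    """Per-bin retention mask from the background signal-to-noise ratio.

    alpha = (n_m - n_b) / n_b; a bin is retained iff alpha >= cutoff
    (the boundary value is retained).  Bins with n_b = 0 have undefined
    alpha and are masked out.
    """
    check_common_grid(sample.wavelength, background.wavelength)
    nb = background.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (sample.counts - nb) / nb
    retained = np.where(nb > 0, alpha >= cutoff, False)
    return retained


def relative_absorbance(
    sample: CountSpectrum,
    background: CountSpectrum,
    reference: CountSpectrum,
    snr_cutoff: float | None = DEFAULT_SNR_CUTOFF,
) -> AbsorbanceSpectrum:
    """Reduce one count triplet to a masked relative-absorbance spectrum.

    Bins where the reference does not rise above the background carry no
    information and are masked.  With ``snr_cutoff`` set (the default), the
    background signal-to-noise criterion is applied as well; pass ``None``
    to skip it.  Values with r > 1 (sample counts below background after
    noise) are clipped to 1; negative r (noise overshoot on near-blank
    samples) is retained as-is so replicate averaging stays unbiased.
    """
    grid = check_common_grid(sample.wavelength, background.wavelength, reference.wavelength)
    nm, nb, nref = sample.counts, background.counts, reference.counts

    denom = nref - nb
    valid = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 - (nm - nb) / denom
    r = np.where(valid, r, np.nan)
    r = np.minimum(r, 1.0)

    mask = valid
    if snr_cutoff is not None:
        mask = mask & snr_mask(sample, background, snr_cutoff)
    return AbsorbanceSpectrum(grid, r, mask=mask)


def aggregate_replicates(replicates: Sequence[AbsorbanceSpectrum]) -> AbsorbanceSpectrum:
    """Bin-wise mean and sample standard deviation over replicate spectra.

    Requires at least two replicates on an identical grid.  A bin is
    retained only if it is retained in every replicate (intersection rule),
    so the reported spread never mixes trusted and untrusted values.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to aggregate")
    grid = check_common_grid(*(rep.wavelength for rep in replicates))
    stack = np.vstack([rep.r for rep in replicates])
    mask = np.logical_and.reduce([rep.mask for rep in replicates])
    with np.errstate(invalid="ignore"):
        mean = stack.mean(axis=0)
        std = stack.std(axis=0, ddof=1)
    return AbsorbanceSpectrum(grid, mean, mask=mask, r_err=std)


def reduce_replicate_triplets(
    triplets: Sequence[tuple[CountSpectrum, CountSpectrum, CountSpectrum]],
    snr_cutoff: float | None = DEFAULT_SNR_CUTOFF,
) -> tuple[AbsorbanceSpectrum, list[AbsorbanceSpectrum]]:
    """Reduce measurement triplets and aggregate them.

    Each triplet may be given in any order; the spectra are dispatched by
    their ``role``.  Returns the aggregate and the individual reduced
    spectra.  With a single triplet the aggregate is that spectrum itself
    (no spread estimate).
    """
    reduced = []
    for triplet in triplets:
        by_role = {spec.role: spec for spec in triplet}
        if set(by_role) != {"sample", "background", "reference"}:
            raise ValueError(
                f"a triplet needs one spectrum per role, got {[s.role for s in triplet]}"
            )
        reduced.append(
            relative_absorbance(
                by_role["sample"], by_role["background"], by_role["reference"],
                snr_cutoff=snr_cutoff,
            )
        )
    if len(reduced) == 1:
        return reduced[0], reduced
    return aggregate_replicates(reduced), reduced
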