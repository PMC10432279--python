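"""Coverage QC and read-count based genetic sexing."""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import INDETERMINATE, MISSING, XX, XY, PseudoHaploidMatrix, ReadCountProfile

#: normalized Y-rate thresholds: below the first -> XX, above the second -> XY
Y_RATIO_FEMALE_MAX = 0.05
Y_RATIO_MALE_MIN = 0.4

#: individuals covered at fewer SNPs than this are excluded
MIN_COVERED_SITES = 20_000


@dataclass(frozen=True)
class SexCall:
    sex: str
    y_rate: float  # Y reads per target bp, relative to the autosomal rate
    x_rate: float


def determine_sex(
    profile: ReadCountProfile,
    female_max: float = Y_RATIO_FEMALE_MAX,
    male_min: float = Y_RATIO_MALE_MIN,
) -> SexCall:
    """Call genetic sex from the relative Y-chromosome read rate.

    Reads are normalized per target base and divided by the autosomal
    per-base rate. A low normalized Y rate indicates two X chromosomes;
    a high one indicates an X/Y karyotype; rates between the thresholds
    are left indeterminate.
    """
    if profile.autosomal_reads == 0:
        raise ValueError("zero autosomal coverage: cannot normalize sex ratios")
    auto_rate = profile.autosomal_reads / profile.autosomal_target_bp
    r_y = (profile.y_reads / profile.y_target_bp) / auto_rate
    r_x = (profile.x_reads / profile.x_target_bp) / auto_rate
    if r_y < female_max:
        sex = XX
    elif r_y > male_min:
        sex = XY
    else:
        sex = INDETERMINATE
    return SexCall(sex=sex, y_rate=float(r_y), x_rate=float(r_x))


def filter_low_coverage(
    matrix: PseudoHaploidMatrix, min_sites: int = MIN_COVERED_SITES
) -> tuple[list[str], dict[str, int]]:
    """Drop individuals covered at fewer than ``min_sites`` SNPs.

    Returns the retained ids (original order) and the covered-site count for
    every individual, retained or not. The boundary is strict: an individual
    covered at exactly ``min_sites`` is kept.
    """
    if matrix.n_individuals == 0:
        raise ValueError("empty matrix")
    counts = matrix.covered_counts()
    count_by_id = {i: int(c) for i, c in zip(matrix.ids, counts)}
    retained = [i for i, c in zip(matrix.ids, counts) if c >= min_sites]
    return retained, count_by_id
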