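"""Published design and read-accounting records of the urban-waterway study.

The sequencing and rainfall totals reported for the 48-sample sediment
survey, kept as data so the derived quantities (trimming retention,
database mapping rate, per-sample depth, rainfall per rainy day) are
always recomputed from the printed inputs rather than stored.
"""

from __future__ import annotations

N_SAMPLES = 48            # 2 land uses x 2 rain events x before/after x 6 reps
N_REPLICATES = 6

RAW_READS = 3_109_452_182        # total raw sequences (both mates)
TRIMMED_READS = 3_023_688_898    # reads surviving quality trimming
MAPPED_READS = 1_460_323_652     # reads mapped against the protein database

#: Annual rainfall totals (mm) and number of rainy days per year.
RAINFALL_MM = {2011: 3_423, 2012: 2_700}
RAINY_DAYS = {2011: 190, 2012: 170}


def trimming_retention_percent() -> float:
    """Percent of raw reads surviving quality trimming."""
    return 100.0 * TRIMMED_READS / RAW_READS


def mapping_rate_percent() -> float:
    """Percent of trimmed reads with a protein-database match."""
    return 100.0 * MAPPED_READS / TRIMMED_READS


def mean_mapped_reads_per_sample() -> float:
    """Average number of database-mapped reads per sample."""
    return MAPPED_READS / N_SAMPLES


def rain_per_rainy_day_mm(year: int) -> float:
    """Average rainfall (mm) per rainy day for a recorded year."""
    return RAINFALL_MM[year] / RAINY_DAYS[year]
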