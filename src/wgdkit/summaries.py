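"""Closed-form desk calculations for genome-report quantities.

LTR insertion ages from terminal-repeat divergence (t = K / 2r), SNP
heterozygosity spacing, assembly/annotation fractions, gene density, and
the flow-cytometry picogram-to-gigabase conversion.  All operations are
pure and rounding conventions match how such figures are conventionally
printed (integer bp spacing, one-decimal percentages, two-decimal Gb).
"""

from __future__ import annotations

from dataclasses import dataclass

#: default nucleotide substitution rate, substitutions per site per year
DEFAULT_SUBSTITUTION_RATE = 1e-8

#: flow-cytometry conversion constant: 1 pg of DNA = 0.978 Gb
PG_TO_GB = 0.978


@dataclass(frozen=True)
class ClockConstant:
    """Nucleotide substitution rate r, substitutions per site per year."""

    r: float = DEFAULT_SUBSTITUTION_RATE

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("substitution rate must be positive")


@dataclass(frozen=True)
class AssemblySummary:
    """Raw inputs for the fraction/density report."""

    total_len: float  # bp
    anchored_len: float = 0.0
    n_genes: int = 0
    n_anchored_genes: int = 0
    repeat_len: float = 0.0
    het_sites: int = 0

    def __post_init__(self):
        if self.anchored_len > self.total_len or self.repeat_len > self.total_len:
            raise ValueError("component length exceeds total length")
        if self.n_anchored_genes > self.n_genes:
            raise ValueError("anchored genes exceed total genes")


def ltr_insertion_time(K: float, clock: ClockConstant = ClockConstant()) -> float:
    """LTR integration time in years: t = K / (2 r).

    K is the substitutions per site between the element's two terminal
    repeats, which are identical at insertion and diverge at rate r each.
    """
    if K < 0:
        raise ValueError("divergence K must be non-negative")
    return K / (2.0 * clock.r)


def het_spacing(het_sites: int, length: float) -> tuple[int | None, float]:
    """Heterozygous-SNP spacing: (bp per site, percentage of sites).

    Returns ``(None, 0.0)`` when there are no heterozygous sites.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if het_sites < 0:
        raise ValueError("het_sites must be non-negative")
    if het_sites == 0:
        return None, 0.0
    return round(length / het_sites), round(100.0 * het_sites / length, 2)


def fraction_pct(part: float, whole: float, digits: int = 1) -> float:
    """Percentage of ``part`` in ``whole``, rounded to ``digits`` decimals."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not (0 <= part <= whole):
        raise ValueError("part must lie in [0, whole]")
    return round(100.0 * part / whole, digits)


def gene_density_kb(total_len: float, n_genes: int) -> float:
    """Average genomic span per gene, in kb (one gene per N kb)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round(total_len / n_genes / 1000.0, 1)


def pg_to_gb(dna_pg_2c: float) -> float:
    """Haploid (1C) genome size in Gb from a 2C flow-cytometry DNA amount."""
    if dna_pg_2c <= 0:
        raise ValueError("DNA amount must be positive")
    return round(dna_pg_2c / 2.0 * PG_TO_GB, 2)


def summary_report(s: AssemblySummary) -> dict:
    """Assemble the standard report from raw summary inputs."""
    # heterozygosity is assessed over the anchored (chromosome-scale) length
    # when one is given, since SNP calling is restricted to placed sequence
    spacing, het_pct = het_spacing(s.het_sites, s.anchored_len or s.total_len)
    report = {
        "anchored_pct": fraction_pct(s.anchored_len, s.total_len),
        "repeat_pct": fraction_pct(s.repeat_len, s.total_len),
        "het_spacing_bp": spacing,
        "het_pct": het_pct,
    }
    if s.n_genes:
        report["gene_density_kb"] = gene_density_kb(s.total_len, s.n_genes)
        report["genes_anchored_pct"] = fraction_pct(s.n_anchored_genes, s.n_genes)
    return report
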