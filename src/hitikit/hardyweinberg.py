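"""Multi-allelic Hardy-Weinberg genotype prediction for edited loci.

Given measured allele-class frequencies p_i (wild-type, mutant, HITI-edited,
INDEL-disrupted, ...), random pairing predicts genotype frequencies p_i^2
for homozygotes and 2 p_i p_j for heterozygotes.  For animals heterozygous
for a dominant mutation, allele frequencies measured in homozygous
wild-type animals are adjusted by halving the wild-type class and assigning
the other half to the mutant allele, leaving edited-class frequencies
unchanged (their total is 1 - wt either way).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

_TOL = 1e-9


class AlleleFrequencyError(ValueError):
    pass


def validate_freqs(freqs: Mapping[str, float]) -> dict[str, float]:
    if not freqs:
        raise AlleleFrequencyError("empty allele frequency vector")
    out = dict(freqs)
    if any(v < -_TOL or v > 1 + _TOL for v in out.values()):
        raise AlleleFrequencyError("frequencies must be in [0, 1]")
    total = sum(out.values())
    if abs(total - 1.0) > 1e-6:
        raise AlleleFrequencyError(f"frequencies sum to {total}, not 1")
    return out


def hw_genotypes(freqs: Mapping[str, float]) -> dict[tuple[str, str], float]:
    """Genotype-frequency table: (i,i) -> p_i^2; (i,j), i<j -> 2 p_i p_j."""
    p = validate_freqs(freqs)
    labels = list(p)
    table: dict[tuple[str, str], float] = {}
    for a in range(len(labels)):
        for b in range(a, len(labels)):
            i, j = labels[a], labels[b]
            table[(i, j)] = p[i] ** 2 if i == j else 2 * p[i] * p[j]
    return table


def heterozygote_adjust(
    measured_in_homozygous_wt: Mapping[str, float],
    mutant_label: str = "P23H",
    wild_type_label: str = "wild_type",
) -> dict[str, float]:
    """Halve the wild-type allele frequency and give the other half to the
    mutant allele (e.g. 86% wt measured in wild-type animals predicts
    43% wt + 43% mutant in heterozygotes); remaining classes are
    renormalised to keep the vector summing to 1 (which preserves their
    measured values, since the non-wt total is unchanged)."""
    p = validate_freqs(measured_in_homozygous_wt)
    if wild_type_label not in p:
        raise AlleleFrequencyError(
            f"wild-type label {wild_type_label!r} absent; cannot halve"
        )
    if p.get(mutant_label, 0.0) > _TOL:
        raise AlleleFrequencyError(
            f"mutant label {mutant_label!r} already has nonzero frequency"
        )
    wt = p[wild_type_label]
    out = {wild_type_label: wt / 2, mutant_label: wt / 2}
    rest = {k: v for k, v in p.items()
            if k not in (wild_type_label, mutant_label)}
    rest_total = sum(rest.values())
    target = 1.0 - wt
    scale = target / rest_total if rest_total > _TOL else 0.0
    for k, v in rest.items():
        out[k] = v * scale
    return out


def genotype_table(table: Mapping[tuple[str, str], float]) -> pd.DataFrame:
    rows = [
        {"allele_1": i, "allele_2": j, "frequency": f}
        for (i, j), f in sorted(table.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)


def read_freqs_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["allele"], df["freq"].astype(float)))


def write_freqs_tsv(freqs: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"allele": list(freqs), "freq": list(freqs.values())}
    ).to_csv(path, sep="\t", index=False)
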