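"""Cross-table CSV dialect and tabular output.

The genotype table dialect has three header rows — marker names, chromosome,
cM position — then one row per male with genotype codes: ``A`` two focal
(donor) alleles or hemizygous focal, ``H`` heterozygous, ``B`` background,
``-`` missing. This mirrors the layout of hand-curated backcross genotype
spreadsheets.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .crosses import MaleGenotype
from .genome import Chromosome, GeneticMap, Marker
from .protocol import InterpolationResult, SexRatioResult, VialSeries

__all__ = [
    "genotypes_to_cross_csv",
    "cross_csv_to_frame",
    "map_from_cross_csv",
    "phenotypes_to_csv",
    "phenotypes_from_csv",
    "vial_series_to_frame",
    "male_summary_frame",
]


def _code(g: MaleGenotype, i: int, focal_line: str) -> str:
    if g.x_linked[i]:
        return "A" if g.maternal[i] == focal_line else "B"
    d = int(g.maternal[i] == focal_line) + int(g.paternal[i] == focal_line)
    return {2: "A", 1: "H", 0: "B"}[d]


def genotypes_to_cross_csv(
    genotypes: list[MaleGenotype],
    gmap: GeneticMap,
    focal_line: str = "alb267",
    ids: list[str] | None = None,
) -> str:
    """Serialize a population in the three-header-row cross CSV dialect."""
    ids = ids or [f"m{i + 1:04d}" for i in range(len(genotypes))]
    buf = io.StringIO()
    buf.write("id," + ",".join(m.name for m in gmap.markers) + "\n")
    buf.write("chromosome," + ",".join(m.chromosome for m in gmap.markers) + "\n")
    buf.write("cM," + ",".join(f"{m.position:g}" for m in gmap.markers) + "\n")
    for mid, g in zip(ids, genotypes):
        buf.write(mid + "," + ",".join(_code(g, i, focal_line) for i in range(gmap.n_markers)) + "\n")
    return buf.getvalue()


def cross_csv_to_frame(text: str) -> pd.DataFrame:
    """Genotype codes as a DataFrame (rows = males, columns = markers)."""
    lines = text.strip().splitlines()
    names = lines[0].split(",")[1:]
    rows = [ln.split(",") for ln in lines[3:]]
    return pd.DataFrame(
        [r[1:] for r in rows], index=[r[0] for r in rows], columns=names
    )


def map_from_cross_csv(text: str) -> GeneticMap:
    """Recover a GeneticMap (markers + inferred lengths) from the dialect."""
    lines = text.strip().splitlines()
    names = lines[0].split(",")[1:]
    chroms = lines[1].split(",")[1:]
    pos = [float(x) for x in lines[2].split(",")[1:]]
    order: list[str] = []
    for c in chroms:
        if c not in order:
            order.append(c)
    markers = [Marker(n, c, p) for n, c, p in zip(names, chroms, pos)]
    lengths = {
        c: max(p for m, p in zip(chroms, pos) if m == c) for c in order
    }
    chromosomes = [Chromosome(c, lengths[c], is_sex_linked=(c == "X-3")) for c in order]
    return GeneticMap(chromosomes, markers)


def phenotypes_to_csv(phenotypes, ids: list[str] | None = None) -> str:
    ids = ids or [f"m{i + 1:04d}" for i in range(len(phenotypes))]
    df = pd.DataFrame(
        {
            "id": ids,
            "T": [p.T for p in phenotypes],
            "females": [p.females for p in phenotypes],
            "males": [p.males for p in phenotypes],
        }
    )
    return df.to_csv(index=False)


def phenotypes_from_csv(text: str):
    from .phenotypes import MalePhenotype

    df = pd.read_csv(io.StringIO(text))
    return [
        MalePhenotype(int(r.T), int(r.females), int(r.males)) for r in df.itertuples()
    ]


def vial_series_to_frame(series_by_male: dict[str, VialSeries]) -> pd.DataFrame:
    rows = []
    for mid, series in series_by_male.items():
        for v in series.vials:
            rows.append(
                {
                    "male_id": mid,
                    "start_day": v.start_day,
                    "n_days": v.n_days,
                    "females": v.females,
                    "males": v.males,
                    "counted": v.counted,
                }
            )
    return pd.DataFrame(rows)


def male_summary_frame(
    ids: list[str],
    interp: list[InterpolationResult],
    sexratio: list[SexRatioResult],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": ids,
            "T_counted": [r.counted_total for r in interp],
            "T_interpolated": [r.total for r in interp],
            "k": [s.k if s.eligible else np.nan for s in sexratio],
            "eligible": [s.eligible for s in sexratio],
        }
    )
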