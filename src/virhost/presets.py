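"""Bundled study presets.

``table2_*`` encodes the published abundance table of the fire-ant
(*Solenopsis invicta*) transcriptome survey that this pipeline reproduces:
thirteen libraries, five candidate viruses (the four-segment tenui-like
SINV-14, the mononegavirus SINV-15, the iflavirus SINV-16, the nege-like
SINV-17 and the partial densovirus SINaDNV) and three housekeeping genes
(cox1, rpl18, eif1-beta), as percentages of each library's reads.  Missing
cells are not-detected.  Per-library total read counts were not published;
the preset assigns fixed realistic totals (tens of millions of reads) so
that exact-mode counts reproduce every printed percentage to well within
0.001 percentage points.

``fig5_spec`` and ``fig1b_genome`` build the synthetic stand-ins for the
compositional-bias PCA groups and the motif-bearing segmented genome.
"""

from __future__ import annotations

from .composition import CODONS
from .io import CountTable, Library, VirusMeta
from .motifs import MOTIF_PRESETS, SegmentedGenome
from .simulate import (
    AbundanceSpec,
    CompositionSpec,
    GroupSpec,
    gen_count_table,
    gen_segmented_genome,
)

__all__ = [
    "TABLE2_LIBRARIES",
    "TABLE2_PERCENT",
    "HOUSEKEEPING",
    "WHOLE_BODY_SINV14_LIBRARIES",
    "table2_libraries",
    "table2_viruses",
    "table2_abundance_spec",
    "table2_counts",
    "table2_printed_abundance",
    "fig5_spec",
    "fig1b_genome",
]

HOUSEKEEPING = ("cox1", "rpl18", "eif1-beta")

# library_id, accession, stage, tissue, origin, assigned total reads
TABLE2_LIBRARIES: list[tuple[str, str, str, str, str, int]] = [
    ("A", "SRX3035962", "larvae", "whole_body", "Mississippi, USA", 41_236_918),
    ("B", "SRX3035961", "larvae", "whole_body", "Mississippi, USA", 38_407_552),
    ("C", "SRX3035960", "larvae", "whole_body", "Mississippi, USA", 44_981_270),
    ("X", "SRX3035959", "pupa", "whole_body", "Mississippi, USA", 36_554_009),
    ("Y", "SRX3035964", "pupa", "whole_body", "Mississippi, USA", 39_118_463),
    ("Z", "SRX3035963", "pupa", "whole_body", "Mississippi, USA", 42_690_114),
    ("Q2", "DRX037806", "adult", "whole_body", "Texas, USA", 33_805_726),
    ("W2", "DRX037809", "adult", "whole_body", "Texas, USA", 35_229_881),
    ("W3", "DRX037810", "adult", "whole_body", "Texas, USA", 37_664_320),
    ("Y05", "SRX5464977", "adult", "brain", "Florida, USA", 28_917_455),
    ("K05", "SRX5464984", "adult", "brain", "Florida, USA", 27_403_168),
    ("CA01", "SRX5464990", "adult", "brain", "Florida, USA", 29_660_842),
    ("2-small", "SRX5822389", "adult", "whole_body", "Taiwan", 31_942_637),
]

#: printed abundance percentages; absent keys are not-detected cells
TABLE2_PERCENT: dict[str, dict[str, float]] = {
    "SINV-14_RNA1": {
        "B": 0.047, "C": 0.046, "Z": 0.374, "Q2": 1.469, "W2": 1.679,
        "W3": 1.658, "Y05": 6.803, "2-small": 0.084,
    },
    "SINV-14_RNA2": {
        "B": 0.019, "C": 0.005, "Z": 0.032, "Q2": 0.055, "W2": 0.006,
        "W3": 0.006, "Y05": 0.941, "2-small": 0.009,
    },
    "SINV-14_RNA3": {
        "B": 0.042, "C": 0.051, "Z": 0.131, "Q2": 0.240, "W2": 0.088,
        "W3": 0.089, "Y05": 0.650, "2-small": 0.017,
    },
    "SINV-14_RNA4": {
        "B": 0.072, "C": 0.048, "Z": 0.089, "Q2": 0.944, "W2": 0.601,
        "W3": 0.619, "Y05": 0.001, "2-small": 0.019,
    },
    "SINV-15": {
        "A": 0.008, "B": 0.013, "C": 0.019, "X": 0.009, "Y": 0.023,
        "Z": 0.039, "Q2": 0.211, "W2": 0.020, "W3": 0.020,
    },
    "SINV-16": {"A": 0.516, "B": 0.327, "C": 0.120},
    "SINV-17": {"A": 0.128, "B": 0.235, "C": 0.281},
    "SINaDNV": {"A": 0.002, "C": 0.002},
    "cox1": {
        "A": 0.3910, "B": 0.7102, "C": 0.4324, "X": 0.2860, "Y": 0.3236,
        "Z": 0.2687, "Q2": 1.0036, "W2": 2.1720, "W3": 1.6576,
        "Y05": 0.4903, "K05": 0.4957, "CA01": 0.4639, "2-small": 0.9619,
    },
    "rpl18": {
        "A": 0.0238, "B": 0.0263, "C": 0.0246, "X": 0.0161, "Y": 0.0153,
        "Z": 0.0135, "Q2": 0.0530, "W2": 0.0342, "W3": 0.0351,
        "Y05": 0.0119, "K05": 0.0141, "CA01": 0.0158, "2-small": 0.0712,
    },
    "eif1-beta": {
        "A": 0.0163, "B": 0.0267, "C": 0.0305, "X": 0.0080, "Y": 0.0089,
        "Z": 0.0090, "Q2": 0.0469, "W2": 0.0113, "W3": 0.0117,
        "Y05": 0.0048, "K05": 0.0046, "CA01": 0.0064, "2-small": 0.0340,
    },
}

#: printed whole-genome totals for the four-segment virus (for golden tests;
#: the pipeline recomputes totals as the sum of segments)
TABLE2_SINV14_TOTAL: dict[str, float] = {
    "B": 0.180, "C": 0.150, "Z": 0.626, "Q2": 2.708, "W2": 2.374,
    "W3": 2.372, "Y05": 8.394, "2-small": 0.130,
}

#: whole-body libraries where the four-segment virus was detected
WHOLE_BODY_SINV14_LIBRARIES = ("B", "C", "Z", "Q2", "W2", "W3", "2-small")


def table2_libraries() -> list[Library]:
    return [
        Library(library_id=l, accession=acc, stage=st, tissue=ti, origin=orig,
                total_reads=tot)
        for l, acc, st, ti, orig, tot in TABLE2_LIBRARIES
    ]


def table2_viruses() -> list[VirusMeta]:
    """Virus metadata with the study's phylogeny/completeness flags.

    All five candidates cluster with insect viruses; only the densovirus
    lacks a complete coding region (partial genome).
    """
    return [
        VirusMeta("SINV-14", tuple(f"SINV-14_RNA{i}" for i in range(1, 5)), True, True),
        VirusMeta("SINV-15", ("SINV-15",), True, True),
        VirusMeta("SINV-16", ("SINV-16",), True, True),
        VirusMeta("SINV-17", ("SINV-17",), True, True),
        VirusMeta("SINaDNV", ("SINaDNV",), False, True),
    ]


def table2_abundance_spec(mode: str = "exact", seed: int = 0) -> AbundanceSpec:
    targets = {
        (feat, lib): pct
        for feat, cells in TABLE2_PERCENT.items()
        for lib, pct in cells.items()
    }
    kinds = {
        feat: ("housekeeping" if feat in HOUSEKEEPING else "virus_segment")
        for feat in TABLE2_PERCENT
    }
    return AbundanceSpec(
        libraries=table2_libraries(), targets=targets, feature_kind=kinds,
        mode=mode, seed=seed,
    )


def table2_counts(mode: str = "exact", seed: int = 0) -> CountTable:
    """The bundled printed-table preset as a count table."""
    return gen_count_table(table2_abundance_spec(mode=mode, seed=seed))


def table2_printed_abundance(include_totals: bool = True):
    """The printed percentages directly as an AbundanceTable (no counts).

    With ``include_totals`` the published whole-genome "Total" column of the
    four-segment virus is carried as feature ``SINV-14`` exactly as printed;
    it can differ from the sum of the printed segment cells by up to 0.001
    (each cell is independently rounded to 3 decimals).
    """
    from .abundance import AbundanceTable

    cells = dict(TABLE2_PERCENT)
    if include_totals:
        cells["SINV-14"] = TABLE2_SINV14_TOTAL
    values = {}
    detected = {}
    lib_ids = [l for l, *_ in TABLE2_LIBRARIES]
    feats = list(cells)
    for feat in feats:
        for lib in lib_ids:
            if lib in cells[feat]:
                values[(feat, lib)] = cells[feat][lib]
                detected[(feat, lib)] = True
            else:
                detected[(feat, lib)] = False
    return AbundanceTable(values=values, detected=detected,
                          feature_ids=feats, library_ids=lib_ids)


def _weights(favoured: dict[str, float], background: float = 0.05) -> dict[str, float]:
    w = {c: background for c in CODONS}
    for codon, weight in favoured.items():
        w[codon] = weight
    for stop in ("TAA", "TAG", "TGA"):
        w[stop] = 0.0
    return w


def fig5_spec(seed: int = 0, n_per_group: int = 12, length: int = 1998) -> CompositionSpec:
    """Three separable compositional regimes mimicking the PCA group layout:
    plant-adapted viruses, non-plant viruses and a focal group with its own
    bias.  Groups favour disjoint codon sets so the planted separation is
    recoverable on the first two components."""
    plant = _weights({"GCA": 3.0, "CCA": 3.0, "ACA": 3.0, "GGA": 3.0,
                      "GAA": 2.0, "CAA": 2.0})
    nonplant = _weights({"GCG": 3.0, "CCG": 3.0, "ACG": 3.0, "GGC": 3.0,
                         "GAG": 2.0, "CAG": 2.0})
    focal = _weights({"GCT": 3.0, "CCT": 3.0, "ACT": 3.0, "GGT": 3.0,
                      "GAT": 2.0, "TGT": 2.0})
    return CompositionSpec(
        groups=[
            GroupSpec("plant_virus", n_per_group, length, plant),
            GroupSpec("non_plant_virus", n_per_group, length, nonplant),
            GroupSpec("focal", max(3, n_per_group // 3), length, focal),
        ],
        seed=seed,
    )


def fig1b_genome(
    preset: str = "canonical",
    mismatches_per_segment=(0, 0, 0, 0),
    seed: int = 0,
) -> SegmentedGenome:
    """A four-segment genome carrying the tenuivirus terminal consensus,
    with segment lengths in the range of the real tenui-like segments."""
    motif5, motif3 = MOTIF_PRESETS[preset]
    return gen_segmented_genome(
        n_segments=4,
        lengths=[8900, 3600, 2300, 1900],
        motif5=motif5,
        motif3=motif3,
        mismatches_per_segment=list(mismatches_per_segment),
        seed=seed,
        virus_id="tenui_like",
    )
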