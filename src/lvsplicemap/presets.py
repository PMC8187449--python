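"""Bundled vector designs and library presets.

The plasmid sequences of the pLV family are not public, but every feature
length that matters for the accounting is known: a 364 nt gag fragment (21 or
60 nt retained in the gag-deletion designs), an 858 nt env fragment containing
the 351 nt RRE, and the LTR R/U5 parts.  The builders below lay those
features out with synthetic, internally consistent absolute coordinates so
that deletion and provirus accounting, simulation and classification can all
run without external data.

The library presets encode, per vector, an isoform mixture whose analytic
splicing statistics (fraction unspliced, splice events per transcript,
per-junction event shares, readthrough fraction) equal the values measured on
the corresponding real libraries.  Junction chains such as SD1-SA7 followed by
CD3-CA6 carry the excess events that make events/transcript exceed the
spliced-read fraction; geometrically this requires SA7 to sit upstream of CD3
within the deletable 3' part of env, which the synthetic layout adopts.
"""

from __future__ import annotations

import zlib

import numpy as np

from .errors import ConfigurationError
from .simulate import Isoform, SimulationConfig
from .vector_model import Feature, VectorGenome

VECTOR_NAMES = (
    "pLV",
    "pLV-gag21",
    "pLV-gag60",
    "pLV-RRE",
    "pLV-RREgag21",
    "pLV-RREgag60",
    "pLV-3'RRE",
    "pLV-gag21-3'RRE",
)

#: library presets with measured splicing statistics (sequenced vectors)
LIBRARY_NAMES = ("pLV", "pLV-gag21", "pLV-RRE", "pLV-RREgag21", "pLV-RREgag60")

_GAG_FULL, _ENV_FULL, _RRE_LEN = 364, 858, 351

# point splice sites attached by (host element, offset); sites hosted in
# HIV-1-derived elements are themselves HIV-1 sequence, the rest (e.g. CA10 in
# the GFP open reading frame) are vector-backbone sites
_POINTS = {
    "leader": [("SD1", 89, "splice_donor", "HIV1"), ("CD2", 189, "splice_donor", "HIV1")],
    "env": [("SA7", 590, "splice_acceptor", "HIV1"), ("CD3", 650, "splice_donor", "HIV1")],
    "CMV": [
        ("CA6", 274, "splice_acceptor", "non-HIV1"),
        ("CA2", 474, "splice_acceptor", "non-HIV1"),
    ],
    "GFP": [
        ("CA9", 24, "splice_acceptor", "non-HIV1"),
        ("CD5", 124, "splice_donor", "non-HIV1"),
        ("CA10", 324, "splice_acceptor", "non-HIV1"),
        ("CA4", 524, "splice_acceptor", "non-HIV1"),
    ],
}

_RRE_OFFSET_IN_ENV = 200  # RRE span inside the full env fragment


def _elements(variant: str) -> list[tuple[str, int, str, str]]:
    if variant not in VECTOR_NAMES:
        raise ConfigurationError(
            f"unknown vector {variant!r}; choose from {', '.join(VECTOR_NAMES)}"
        )
    gag = _GAG_FULL
    if "gag21" in variant:
        gag = 21
    elif "gag60" in variant:
        gag = 60
    rre_at_3prime = variant.endswith("3'RRE")
    env: int | None = _ENV_FULL
    if variant.startswith("pLV-RRE"):
        env = _RRE_LEN  # env fragment reduced to the RRE alone
    elif rre_at_3prime:
        env = None  # env removed; RRE reinserted downstream of the 3' R

    parts: list[tuple[str, int, str, str]] = [
        ("RSV", 230, "other", "non-HIV1"),
        ("R5", 97, "ltr_part", "HIV1"),
        ("U5", 84, "ltr_part", "HIV1"),
        ("leader", 290, "hiv1_span", "HIV1"),
        ("gag", gag, "hiv1_span", "HIV1"),
        ("spacer", 135, "other", "non-HIV1"),
    ]
    if env is not None:
        parts.append(("env", env, "hiv1_span", "HIV1"))
    parts += [
        ("cPPT", 118, "hiv1_span", "HIV1"),
        ("CMV", 600, "other", "non-HIV1"),
        ("GFP", 720, "transgene_span", "non-HIV1"),
        ("WPRE", 600, "other", "non-HIV1"),
        ("dU3", 18, "ltr_part", "HIV1"),
        ("R3", 97, "ltr_part", "HIV1"),
    ]
    if rre_at_3prime:
        parts.append(("RRE", _RRE_LEN, "hiv1_span", "HIV1"))
    parts.append(("SV40pA", 140, "other", "non-HIV1"))
    parts.append(("plasmid", 660, "other", "non-HIV1"))
    return parts


def _synthetic_sequence(name: str, length: int) -> str:
    rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_vector(variant: str, with_sequence: bool = True) -> VectorGenome:
    """Construct one of the bundled vector genome designs."""
    features: list[Feature] = []
    pos = 0
    r3_end = None
    env_full = None
    for name, length, kind, origin in _elements(variant):
        start, end = pos, pos + length
        features.append(Feature(name=name, start=start, end=end, kind=kind, origin=origin))
        if name == "env":
            env_full = length == _ENV_FULL
            rre_off = _RRE_OFFSET_IN_ENV if env_full else 0
            features.append(
                Feature("RRE", start + rre_off, start + rre_off + _RRE_LEN, "hiv1_span", "HIV1")
            )
        if name in _POINTS and (name != "env" or env_full):
            for pname, off, pkind, porigin in _POINTS[name]:
                features.append(Feature(pname, start + off, start + off + 1, pkind, porigin))
        if name == "R3":
            r3_end = end
        pos = end
    assert r3_end is not None
    seq = _synthetic_sequence(variant, pos) if with_sequence else None
    return VectorGenome(name=variant, length=pos, features=features, r3_end=r3_end, sequence=seq)


# ---------------------------------------------------------------------------
# Library isoform mixtures.
#
# Weights are solved from the measured per-library statistics:
#   unspliced fraction u, splice events per transcript E, per-junction event
#   shares p_j.  Single-junction isoforms carry most junctions; two-junction
#   chains [SD1-SA7, CD3-CAx] supply the extra E - (1 - u) events where the
#   measured E exceeds the spliced-read fraction.  Minor junctions absorb the
#   share remainder that the measured table leaves unannotated.
#
# For pLV-RRE the measured pair (u = 0.153, E = 0.83) is infeasible because a
# spliced read has at least one junction (E >= 1 - u = 0.847); the preset
# keeps u and uses the feasible minimum E = 0.847.
# ---------------------------------------------------------------------------

_LIBRARIES: dict[str, dict] = {
    "pLV": {
        "unspliced": 0.049,
        "readthrough": 0.29,
        "isoforms": [
            (("SD1-SA7",), 0.45594),
            (("SD1-CA6",), 0.14985),
            (("SD1-CA9",), 0.010989),
            (("SD1-CA10",), 0.093795),
            (("SD1-SA7", "CD3-CA6"), 0.0999),
            (("SD1-SA7", "CD3-CA10"), 0.056388),
            (("SD1-SA7", "CD3-CA9"), 0.002712),
            (("SD1-CA2",), 0.041426),
            (("SD1-CA4",), 0.025),
            (("CD2-CA10",), 0.015),
        ],
    },
    "pLV-gag21": {
        "unspliced": 0.0571,
        "readthrough": 0.30,
        "isoforms": [
            (("SD1-SA7",), 0.4457),
            (("SD1-CA6",), 0.14351),
            (("SD1-CA9",), 0.010961),
            (("SD1-CA10",), 0.078535),
            (("SD1-SA7", "CD3-CA6"), 0.12204),
            (("SD1-SA7", "CD3-CA10"), 0.063054),
            (("SD1-SA7", "CD3-CA9"), 0.002006),
            (("SD1-CA2",), 0.040094),
            (("SD1-CA4",), 0.022),
            (("CD2-CA10",), 0.015),
        ],
    },
    "pLV-RRE": {
        "unspliced": 0.153,
        "readthrough": 0.28,
        "isoforms": [
            (("SD1-CA6",), 0.193116),
            (("SD1-CA9",), 0.10164),
            (("SD1-CA10",), 0.431123),
            (("SD1-CA2",), 0.06),
            (("SD1-CA4",), 0.045),
            (("CD2-CA10",), 0.016121),
        ],
    },
    "pLV-RREgag21": {
        "unspliced": 0.121,
        "readthrough": 0.34,
        "isoforms": [
            (("SD1-CA6",), 0.19402),
            (("SD1-CA9",), 0.09313),
            (("SD1-CA10",), 0.43521),
            (("SD1-CA9", "CD5-CA10"), 0.011),
            (("SD1-CA2",), 0.075),
            (("SD1-CA4",), 0.05),
            (("CD2-CA10",), 0.02064),
        ],
    },
    "pLV-RREgag60": {
        "unspliced": 0.102,
        "readthrough": 0.34,
        "isoforms": [
            (("SD1-CA6",), 0.2002),
            (("SD1-CA9",), 0.075451),
            (("SD1-CA10",), 0.45318),
            (("SD1-CA9", "CD5-CA10"), 0.012),
            (("SD1-CA2",), 0.08),
            (("SD1-CA4",), 0.05),
            (("CD2-CA10",), 0.027169),
        ],
    },
}


def _resolve_junction(genome: VectorGenome, label: str) -> tuple[int, int]:
    donor_name, acceptor_name = label.split("-")
    donor = genome.feature(donor_name).start
    acceptor = genome.feature(acceptor_name).start
    return donor, acceptor


def library_isoforms(variant: str) -> list[Isoform]:
    """The isoform mixture (with resolved coordinates) for a sequenced vector."""
    if variant not in _LIBRARIES:
        raise ConfigurationError(
            f"no library preset for {variant!r}; presets exist for {', '.join(_LIBRARIES)}"
        )
    genome = build_vector(variant, with_sequence=False)
    spec = _LIBRARIES[variant]
    isoforms = [Isoform(name="unspliced", junctions=(), weight=spec["unspliced"])]
    for chain, weight in spec["isoforms"]:
        junctions = tuple(_resolve_junction(genome, lbl) for lbl in chain)
        isoforms.append(Isoform(name="+".join(chain), junctions=junctions, weight=weight))
    return isoforms


def library_config(
    variant: str,
    n_reads: int = 5000,
    seed: int = 0,
    wobble_sd: float = 4.0,
    truncation_mean: float = 1000.0,
    readthrough_extension: tuple[int, int] = (50, 400),
) -> SimulationConfig:
    """A ready-to-run simulation preset emulating one sequenced library."""
    genome = build_vector(variant)
    spec = _LIBRARIES[variant]
    return SimulationConfig(
        genome=genome,
        isoforms=library_isoforms(variant),
        readthrough_prob=spec["readthrough"],
        readthrough_extension=readthrough_extension,
        truncation_mean=truncation_mean,
        wobble_sd=wobble_sd,
        n_reads=n_reads,
        seed=seed,
    )
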