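"""Self-contained fixture networks, tracer catalogues, and manifests.

Every stage of the tracer-design workflow is testable without external data:
the generators below emit small, deterministic models (as validated
:class:`~redflux.model.NetworkModel` objects *and* as FluxML-subset XML
text), matching tracer catalogues (YAML), and a manifest of ground-truth
facts that the owning modules re-verify in the test suite.

* :func:`make_chain` — a linear pathway with identity atom maps; its
  terminal MID equals the substrate distribution and the labeling Jacobian
  is exactly zero (labeling depends on flux ratios only).
* :func:`make_branch_cycle` — two substrates feeding a split/condense motif
  with one bidirectional step; the all-unlabeled mixture is guaranteed
  information-free at the full design size while the manifest's informative
  mixture identifies the maximal active set.
* :func:`make_clavam_analog` — a reduced two-substrate analog of a
  glycerol/arginine antibiotic-producer scenario (glycolysis-, pentose-
  phosphate-, TCA-, anaplerosis-, urea-cycle- and product-pathway-like
  blocks).  Stoichiometry and most prices are synthetic; only the two
  published tracer prices (0.36 $/g for the unlabeled 3-carbon substrate,
  3,449 $/g for the fully labeled 5-carbon substrate) are carried over.  It
  does not claim to reproduce any published organism-scale model.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

from .model import (
    ErrorModel,
    LinearConstraint,
    MeasurementGroup,
    MeasurementSpec,
    Metabolite,
    Mixture,
    NetworkModel,
    Normalization,
    RateMeasurement,
    Reaction,
    TracerSpecies,
    serialize_model,
    serialize_tracer_spec,
)

__all__ = ["FixtureManifest", "make_chain", "make_branch_cycle", "make_clavam_analog"]


@dataclass
class FixtureManifest:
    """A generated fixture: model + tracer catalogue + verifiable facts."""

    name: str
    model: NetworkModel
    catalogue: dict[str, list[TracerSpecies]]
    facts: dict = field(default_factory=dict)

    @property
    def model_xml(self) -> str:
        return serialize_model(self.model)

    @property
    def tracer_yaml(self) -> str:
        return serialize_tracer_spec(self.catalogue)

    def reference_mixture(self) -> Mixture:
        return Mixture.from_dict(self.facts["reference_mixture"]).validate()

    def write(self, directory) -> dict[str, str]:
        """Emit <name>.fml, <name>_tracers.yaml and <name>_manifest.json."""
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "model": str(d / f"{self.name}.fml"),
            "tracers": str(d / f"{self.name}_tracers.yaml"),
            "manifest": str(d / f"{self.name}_manifest.json"),
        }
        pathlib.Path(paths["model"]).write_text(self.model_xml)
        pathlib.Path(paths["tracers"]).write_text(self.tracer_yaml)
        pathlib.Path(paths["manifest"]).write_text(
            json.dumps({"name": self.name, "facts": self.facts}, indent=2)
        )
        return paths


def _groups(*specs):
    out = []
    for gid, met, positions, k in specs:
        out.append(
            MeasurementGroup(
                id=gid,
                metabolite=met,
                positions=tuple(p - 1 for p in positions),
                shifts=tuple(range(k + 1)),
            )
        )
    return tuple(out)


def make_chain(n_steps: int = 3, carbons: int = 2) -> FixtureManifest:
    """Linear pathway S -> M1 -> ... -> P with identity atom maps.

    One free net flux (the uptake, declared as the normalization scale but
    not pinned, so the polytope is a 1-D interval); no exchange coordinates.
    The terminal fragment's MID equals the substrate's isotopomer
    distribution for any mixture, and the labeling Jacobian vanishes.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    atoms = "".join(chr(ord("a") + i) for i in range(carbons))
    mets = [Metabolite("S", carbons, "input")]
    for i in range(1, n_steps):
        mets.append(Metabolite(f"M{i}", carbons, "intra"))
    mets.append(Metabolite("P", carbons, "output"))
    pools = [m.id for m in mets]
    reactions = tuple(
        Reaction(
            id=f"r{i + 1}",
            educts=((pools[i], atoms),),
            products=((pools[i + 1], atoms),),
        )
        for i in range(n_steps)
    )
    model = NetworkModel(
        metabolites=tuple(mets),
        reactions=reactions,
        net_constraints=(LinearConstraint((("r1", 1.0),), "ge", 1.0),),
        xch_constraints=(),
        net_bounds=(-100.0, 100.0),
        xch_bounds=(0.0, 200.0),
        measurement=MeasurementSpec(
            groups=_groups(("ms_P", "P", tuple(range(1, carbons + 1)), carbons)),
            error_model=ErrorModel(),
            rates=(RateMeasurement("r1", 100.0, 5.0),),
        ),
        normalization=Normalization(flux="r1", value=100.0, fixed=False),
        name=f"chain{n_steps}x{carbons}",
    ).validate()
    catalogue = {
        "S": [
            TracerSpecies("S", "U", (1,) * carbons, 100.0, 100.0),
            TracerSpecies("S", "1-13C1", (1,) + (0,) * (carbons - 1), 100.0, 40.0),
            TracerSpecies("S", "12C", (0,) * carbons, 100.0, 0.5),
        ]
    }
    facts = {
        "n_metabolites": len(mets),
        "n_reactions": n_steps,
        "free_net": 1,
        "free_xch": 0,
        "terminal_mid_equals_substrate": True,
        "labeling_jacobian_zero": True,
        "reference_mixture": {"S": [0.5, 0.0, 0.5]},
    }
    return FixtureManifest("chain", model, catalogue, facts)


def make_branch_cycle() -> FixtureManifest:
    """Two-substrate split/condense motif with one bidirectional step.

    A 3-carbon substrate is cleaved (A -> B + C), recondensed (B + C <-> E,
    the exchange coordinate) and bypassed (A -> E with a carbon permutation,
    which makes the exchange flux observable); a 2-carbon substrate feeds B.
    Four free coordinates (3 net + 1 exchange).  The manifest names a
    guaranteed information-free mixture (all unlabeled: the labeling rows of
    the FIM vanish, leaving only the two rate measurements) and an
    informative mixture that attains the fixture's maximal identifiable
    design size on every flux sample.
    """
    mets = (
        Metabolite("SA", 3, "input"),
        Metabolite("SB", 2, "input"),
        Metabolite("A", 3, "intra"),
        Metabolite("B", 2, "intra"),
        Metabolite("C", 1, "intra"),
        Metabolite("E", 3, "intra"),
        Metabolite("P", 3, "output"),
        Metabolite("R", 2, "output"),
        Metabolite("Q", 1, "output"),
    )
    reactions = (
        Reaction("upt_a", (("SA", "abc"),), (("A", "abc"),)),
        Reaction("upt_b", (("SB", "ab"),), (("B", "ab"),)),
        Reaction("split", (("A", "abc"),), (("B", "ab"), ("C", "c"))),
        Reaction("alt", (("A", "abc"),), (("E", "acb"),)),
        Reaction("cond", (("B", "ab"), ("C", "c")), (("E", "abc"),), bidirectional=True),
        Reaction("out_e", (("E", "abc"),), (("P", "abc"),)),
        Reaction("out_b", (("B", "ab"),), (("R", "ab"),)),
        Reaction("out_c", (("C", "a"),), (("Q", "a"),)),
    )
    model = NetworkModel(
        metabolites=mets,
        reactions=reactions,
        net_constraints=(
            LinearConstraint((("split", 1.0),), "ge", 5.0),
            LinearConstraint((("alt", 1.0),), "ge", 5.0),
            LinearConstraint((("out_c", 1.0),), "ge", 1.0),
            LinearConstraint((("out_b", 1.0),), "ge", 1.0),
            LinearConstraint((("upt_b", 1.0),), "ge", 1.0),
        ),
        xch_constraints=(),
        net_bounds=(-100.0, 100.0),
        xch_bounds=(0.0, 200.0),
        measurement=MeasurementSpec(
            groups=_groups(
                ("ms_P", "P", (1, 2, 3), 3),
                ("ms_P12", "P", (1, 2), 2),
                ("ms_R", "R", (1, 2), 2),
                ("ms_Q", "Q", (1,), 1),
            ),
            error_model=ErrorModel(),
            rates=(
                RateMeasurement("upt_b", 20.0, 1.0),
                RateMeasurement("out_e", 90.0, 4.5),
            ),
        ),
        normalization=Normalization(flux="upt_a", value=100.0, fixed=True),
        name="branch_cycle",
    ).validate()
    catalogue = {
        "SA": [
            TracerSpecies("SA", "U-13C3", (1, 1, 1), 99.0, 120.0),
            TracerSpecies("SA", "1-13C1", (1, 0, 0), 99.0, 45.0),
            TracerSpecies("SA", "12C", (0, 0, 0), 99.0, 0.4),
        ],
        "SB": [
            TracerSpecies("SB", "U-13C2", (1, 1), 99.0, 210.0),
            TracerSpecies("SB", "1-13C1", (1, 0), 99.0, 80.0),
            TracerSpecies("SB", "12C", (0, 0), 99.0, 0.6),
        ],
    }
    facts = {
        "n_metabolites": len(mets),
        "n_reactions": len(reactions),
        "free_net": 3,
        "free_xch": 1,
        "singular_mixture": {"SA": [0.0, 0.0, 1.0], "SB": [0.0, 0.0, 1.0]},
        "informative_mixture": {"SA": [0.5, 0.0, 0.5], "SB": [0.0, 1.0, 0.0]},
        # labeling depends on each pool's input-flux ratios only, which caps
        # the identifiable set at 3 of the 4 free coordinates for every
        # mixture; the informative mixture attains that cap on all samples
        "informative_n_act": 3,
        "reference_mixture": {"SA": [0.0, 1.0, 0.0], "SB": [1.0, 0.0, 0.0]},
    }
    return FixtureManifest("branch_cycle", model, catalogue, facts)


def make_clavam_analog() -> FixtureManifest:
    """Reduced two-substrate analog of a glycerol/arginine producer scenario.

    3-carbon substrate GLX (glycerol-like, uptake pinned to 100) and
    5-carbon substrate AGX (arginine-like, uptake below 3% of GLX) feed
    glycolysis-, pentose-phosphate-, TCA-, anaplerosis- and urea-cycle-like
    blocks plus an 8-carbon condensation product pathway.  12 balanced
    pools, 18 reactions (2 bidirectional) -> 5 free net + 2 exchange
    coordinates.  Fragment measurements carry the standard affine GC-MS
    error model.  Synthetic stoichiometry and prices except the two
    published price points; see the module docstring.
    """
    mets = (
        Metabolite("GLX", 3, "input"),
        Metabolite("AGX", 5, "input"),
        Metabolite("G3", 3), Metabolite("PY", 3), Metabolite("AC", 2),
        Metabolite("OA", 4), Metabolite("CI", 6), Metabolite("KG", 5),
        Metabolite("SU", 4), Metabolite("P5", 5), Metabolite("AA", 5),
        Metabolite("OR", 4), Metabolite("CV", 8), Metabolite("CO2", 1),
        Metabolite("CVX", 8, "output"), Metabolite("BMP", 3, "output"),
        Metabolite("BMO", 4, "output"), Metabolite("BM5", 5, "output"),
        Metabolite("CO2X", 1, "output"),
    )
    reactions = (
        Reaction("upt_g", (("GLX", "abc"),), (("G3", "abc"),)),
        Reaction("upt_a", (("AGX", "abcde"),), (("AA", "abcde"),)),
        Reaction("emp", (("G3", "abc"),), (("PY", "abc"),), bidirectional=True),
        Reaction("ppp", (("G3", "abc"), ("G3", "def")),
                 (("P5", "abcde"), ("CO2", "f"))),
        Reaction("pdh", (("PY", "abc"),), (("AC", "bc"), ("CO2", "a"))),
        Reaction("tca1", (("AC", "ab"), ("OA", "cdef")), (("CI", "abcdef"),)),
        Reaction("tca2", (("CI", "abcdef"),), (("KG", "abcde"), ("CO2", "f"))),
        Reaction("tca3", (("KG", "abcde"),), (("SU", "bcde"), ("CO2", "a"))),
        Reaction("tca4", (("SU", "abcd"),), (("OA", "abcd"),), bidirectional=True),
        Reaction("ana", (("PY", "abc"), ("CO2", "d")), (("OA", "abcd"),)),
        Reaction("ure1", (("AA", "abcde"),), (("OR", "abcd"), ("CO2", "e"))),
        Reaction("ure2", (("OR", "abcd"),), (("OA", "abcd"),)),
        Reaction("clv", (("G3", "abc"), ("AA", "defgh")), (("CV", "abcdefgh"),)),
        Reaction("cv_out", (("CV", "abcdefgh"),), (("CVX", "abcdefgh"),)),
        Reaction("bm_py", (("PY", "abc"),), (("BMP", "abc"),)),
        Reaction("bm_oa", (("OA", "abcd"),), (("BMO", "abcd"),)),
        Reaction("bm_p5", (("P5", "abcde"),), (("BM5", "abcde"),)),
        Reaction("co2_out", (("CO2", "a"),), (("CO2X", "a"),)),
    )
    model = NetworkModel(
        metabolites=mets,
        reactions=reactions,
        net_constraints=(
            # keep every measured pool's throughput strictly positive
            LinearConstraint((("upt_a", 1.0),), "le", 3.0),
            LinearConstraint((("upt_a", 1.0),), "ge", 0.5),
            LinearConstraint((("ppp", 1.0),), "ge", 0.5),
            LinearConstraint((("pdh", 1.0),), "ge", 1.0),
            LinearConstraint((("clv", 1.0),), "ge", 0.1),
            LinearConstraint((("ure1", 1.0),), "ge", 0.1),
        ),
        xch_constraints=(),
        net_bounds=(-100.0, 100.0),
        xch_bounds=(0.0, 200.0),
        measurement=MeasurementSpec(
            groups=_groups(
                ("ms_PY", "PY", (1, 2, 3), 3),
                ("ms_OA", "OA", (1, 2, 3, 4), 4),
                ("ms_OA12", "OA", (1, 2), 2),
                ("ms_KG", "KG", (1, 2, 3, 4, 5), 5),
                ("ms_SU", "SU", (1, 2, 3, 4), 4),
                ("ms_AA", "AA", (1, 2, 3, 4, 5), 5),
                ("ms_AA25", "AA", (2, 3, 4, 5), 4),
                ("ms_P5", "P5", (1, 2, 3, 4, 5), 5),
                ("ms_CV", "CV", (1, 2, 3, 4, 5, 6, 7, 8), 8),
                ("ms_CV13", "CV", (1, 2, 3), 3),
            ),
            error_model=ErrorModel(),
            rates=(
                RateMeasurement("upt_a", 2.0, 0.1),
                RateMeasurement("cv_out", 1.0, 0.05),
                RateMeasurement("co2_out", 150.0, 30.0),
            ),
        ),
        normalization=Normalization(flux="upt_g", value=100.0, fixed=True),
        name="clavam_analog",
    ).validate()
    catalogue = {
        "GLX": [
            TracerSpecies("GLX", "U-13C3", (1, 1, 1), 99.0, 110.0),
            TracerSpecies("GLX", "1,3-13C2", (1, 0, 1), 99.0, 165.0),
            TracerSpecies("GLX", "2-13C1", (0, 1, 0), 99.0, 99.0),
            TracerSpecies("GLX", "12C", (0, 0, 0), 99.0, 0.36),
        ],
        "AGX": [
            TracerSpecies("AGX", "U-13C5", (1, 1, 1, 1, 1), 99.0, 3449.0),
            TracerSpecies("AGX", "5-13C1", (0, 0, 0, 0, 1), 99.0, 1150.0),
            TracerSpecies("AGX", "12C", (0, 0, 0, 0, 0), 99.0, 0.9),
        ],
    }
    facts = {
        "n_metabolites": len(mets),
        "n_reactions": len(reactions),
        "free_net": 5,
        "free_xch": 2,
        "species_counts": {"GLX": 4, "AGX": 3},
        "grid_counts_at_10pct": {"GLX": 286, "AGX": 66, "total": 18876},
        "synthetic_prices": True,
        "published_prices": {"GLX/12C": 0.36, "AGX/U-13C5": 3449.0},
        # chemostat settings: g/L concentrations, 1/h dilution, L volume
        "amounts_config": {
            "medium_concentrations": {"GLX": 20.0, "AGX": 0.17},
            "dilution_rate": 0.03,
            "volume": 0.25,
            "residence_times": 5.0,
        },
        "reference_mixture": {
            "GLX": [0.0, 0.0, 1.0, 0.0],
            "AGX": [0.0, 1.0, 0.0],
        },
    }
    return FixtureManifest("clavam_analog", model, catalogue, facts)
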