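"""Network model, measurement configuration, and tracer catalogue.

This module parses and represents everything the tracer-design workflow needs
to know about a :sup:`13`\\ C-MFA study:

* the metabolic network — metabolite pools, reactions with per-carbon atom
  transitions, linear flux constraints;
* the measurement configuration — GC-MS mass-isotopomer groups with an affine
  error model, plus extracellular rate measurements;
* the tracer catalogue — per substrate, the purchasable isotopic species with
  their positional labeling patterns, purities (atom%) and prices ($/g).

Models are read from a documented subset of the FluxML XML dialect::

    <fluxml>
      <reactionnetwork>
        <metabolitepools>
          <pool id="A" atoms="3" type="input"/>   <!-- input | intra | output -->
          <pool id="B" atoms="3"/>                <!-- default: intra -->
        </metabolitepools>
        <reaction id="v1" bidirectional="true">
          <reduct id="A" cx="abc"/>               <!-- one char per carbon -->
          <rproduct id="B" cx="abc"/>
        </reaction>
      </reactionnetwork>
      <constraints>
        <net><bounds lo="-100" hi="100"/><textual>v1 = 100</textual></net>
        <xch><bounds lo="0" hi="200"/></xch>
      </constraints>
      <measurement>
        <mgroup id="ms_B" spec="B[1,2,3]#M0,1,2,3"/>
        <errormodel slope="4.120e-2" intercept="6.655e-3"/>
        <rate flux="v2" value="3.0" stddev="0.15"/>
      </measurement>
      <normalization flux="v1" value="100" fixed="true"/>
    </fluxml>

Stoichiometric coefficients are expressed by repeating ``reduct``/``rproduct``
elements (one element per molecule occurrence), which keeps atom maps
unambiguous.  Carbon positions are 1-based in files and 0-based internally;
the parser owns that boundary.  Atom maps must be bijections between the educt
and product carbon multisets (carbon conservation) — violations raise
:class:`CarbonBalanceError`.

Tracer catalogues are read from YAML or an equivalent XML form; see
:func:`parse_tracer_spec`.
"""

from __future__ import annotations



from dataclasses import dataclass

import numpy as np
import yaml
from lxml import etree

__all__ = [
    "ModelError",
    "ParseError",
    "CarbonBalanceError",
    "DanglingReferenceError",
    "TracerSpecError",
    "Metabolite",
    "Reaction",
    "LinearConstraint",
    "MeasurementGroup",
    "ErrorModel",
    "RateMeasurement",
    "MeasurementSpec",
    "Normalization",
    "NetworkModel",
    "TracerSpecies",
    "Mixture",
    "parse_model",
    "load_model",
    "serialize_model",
    "parse_tracer_spec",
    "species_isotopomer_distribution",
    "substrate_isotopomer_distribution",
]

#: Default probability that a nominally unlabeled carbon is 13C.  The natural
#: abundance of 13C is ~1.07 atom%; the default keeps the background at zero
#: because the GC-MS error model is taken to absorb natural-abundance effects.
NATURAL_ABUNDANCE_13C = 0.0107


class ModelError(ValueError):
    """Base class for model specification problems."""


class ParseError(ModelError):
    """Malformed document or unknown required element."""


class CarbonBalanceError(ModelError):
    """Atom map is not a bijection between educt and product carbons."""


class DanglingReferenceError(ModelError):
    """A referenced metabolite or flux id does not resolve."""


class TracerSpecError(ModelError):
    """Invalid tracer catalogue entry."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    role: str = "intra"  # "input" | "intra" | "output"

    @property
    def is_balanced(self) -> bool:
        """Whether the pool is mass balanced (intracellular)."""
        return self.role == "intra"

    def __post_init__(self):
        if self.n_carbons < 0:
            raise ModelError(f"metabolite {self.id!r}: n_carbons must be >= 0")
        if self.role not in ("input", "intra", "output"):
            raise ModelError(f"metabolite {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A reaction with per-occurrence atom transition strings.

    ``educts`` and ``products`` are tuples of ``(metabolite_id, atoms)`` where
    ``atoms`` is one label character per carbon.  Shared labels define the
    carbon mapping; the multiset of educt labels must equal the product labels
    and labels must be unique within each side.
    """

    id: str
    educts: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]
    bidirectional: bool = False

    def stoichiometry(self) -> dict[str, float]:
        """Net stoichiometric coefficients (products positive)."""
        coeffs: dict[str, float] = {}
        for met, _ in self.educts:
            coeffs[met] = coeffs.get(met, 0.0) - 1.0
        for met, _ in self.products:
            coeffs[met] = coeffs.get(met, 0.0) + 1.0
        return coeffs


@dataclass(frozen=True)
class LinearConstraint:
    """A linear constraint ``sum(coeffs[f] * v_f)  rel  rhs`` on net or xch fluxes."""

    coeffs: tuple[tuple[str, float], ...]
    relation: str  # "eq" | "le" | "ge"
    rhs: float

    def as_le(self) -> "LinearConstraint":
        if self.relation == "ge":
            return LinearConstraint(
                tuple((f, -c) for f, c in self.coeffs), "le", -self.rhs
            )
        return self


@dataclass(frozen=True)
class MeasurementGroup:
    """A GC-MS fragment with observed mass shifts.

    ``positions`` are 0-based carbon indices on ``metabolite``; ``shifts`` the
    observed mass traces (m+0 ... m+k, or a contiguous subset).
    """

    id: str
    metabolite: str
    positions: tuple[int, ...]
    shifts: tuple[int, ...]


@dataclass(frozen=True)
class ErrorModel:
    """Affine standard-deviation model for labeling measurements."""

    slope: float = 4.120e-2
    intercept: float = 6.655e-3

    def sigma(self, y):
        return self.slope * np.asarray(y, dtype=float) + self.intercept


@dataclass(frozen=True)
class RateMeasurement:
    flux: str
    value: float
    stddev: float


@dataclass(frozen=True)
class MeasurementSpec:
    groups: tuple[MeasurementGroup, ...]
    error_model: ErrorModel
    rates: tuple[RateMeasurement, ...] = ()


@dataclass(frozen=True)
class Normalization:
    """The flux all others are scaled to (e.g. substrate uptake = 100).

    ``fixed`` pins the flux to ``value`` with an equality constraint; when
    False the flux only declares the reporting scale and remains free.
    """

    flux: str
    value: float = 100.0
    fixed: bool = True


@dataclass(frozen=True)
class NetworkModel:
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    net_constraints: tuple[LinearConstraint, ...]
    xch_constraints: tuple[LinearConstraint, ...]
    net_bounds: tuple[float, float]
    xch_bounds: tuple[float, float]
    measurement: MeasurementSpec
    normalization: Normalization
    name: str = "model"

    # -- lookups ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise DanglingReferenceError(f"unknown metabolite {met_id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise DanglingReferenceError(f"unknown reaction {rxn_id!r}")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def balanced_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.is_balanced]

    @property
    def substrates(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.role == "input"]

    @property
    def bidirectional_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.bidirectional]

    # -- validation -------------------------------------------------------
    def validate(self) -> "NetworkModel":
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelError("duplicate reaction ids")
        by_id = {m.id: m for m in self.metabolites}
        for rxn in self.reactions:
            self._validate_reaction(rxn, by_id)
        for con in self.net_constraints + self.xch_constraints:
            for flux, _ in con.coeffs:
                if flux not in rids:
                    raise DanglingReferenceError(
                        f"constraint references unknown flux {flux!r}"
                    )
        for con in self.xch_constraints:
            for flux, _ in con.coeffs:
                if not self.reaction(flux).bidirectional:
                    raise ModelError(
                        f"xch constraint on unidirectional reaction {flux!r}"
                    )
        for grp in self.measurement.groups:
            met = by_id.get(grp.metabolite)
            if met is None:
                raise DanglingReferenceError(
                    f"measurement group {grp.id!r} references unknown "
                    f"metabolite {grp.metabolite!r}"
                )
            if len(set(grp.positions)) != len(grp.positions):
                raise ModelError(f"group {grp.id!r}: duplicate carbon positions")
            if any(p < 0 or p >= met.n_carbons for p in grp.positions):
                raise ModelError(
                    f"group {grp.id!r}: carbon position outside 1..{met.n_carbons}"
                )
            k = len(grp.positions)
            if not grp.shifts:
                raise ModelError(f"group {grp.id!r}: no mass shifts")
            if any(s < 0 or s > k for s in grp.shifts):
                raise ModelError(f"group {grp.id!r}: mass shift outside 0..{k}")
            if list(grp.shifts) != list(
                range(grp.shifts[0], grp.shifts[0] + len(grp.shifts))
            ):
                raise ModelError(f"group {grp.id!r}: mass shifts not contiguous")
        for rate in self.measurement.rates:
            if rate.flux not in rids:
                raise DanglingReferenceError(
                    f"rate measurement references unknown flux {rate.flux!r}"
                )
            if rate.stddev <= 0:
                raise ModelError(f"rate {rate.flux!r}: stddev must be > 0")
        if self.normalization.flux not in rids:
            raise DanglingReferenceError(
                f"normalization references unknown flux {self.normalization.flux!r}"
            )
        return self

    @staticmethod
    def _validate_reaction(rxn: Reaction, by_id: dict[str, Metabolite]) -> None:
        educt_labels: list[str] = []
        product_labels: list[str] = []
        for side, labels in (("educt", educt_labels), ("product", product_labels)):
            occs = rxn.educts if side == "educt" else rxn.products
            for met_id, atoms in occs:
                met = by_id.get(met_id)
                if met is None:
                    raise DanglingReferenceError(
                        f"reaction {rxn.id!r}: unknown metabolite {met_id!r}"
                    )
                if len(atoms) != met.n_carbons:
                    raise CarbonBalanceError(
                        f"reaction {rxn.id!r}: {met_id!r} has {met.n_carbons} "
                        f"carbons but atom string {atoms!r}"
                    )
                labels.extend(atoms)
        if len(set(educt_labels)) != len(educt_labels):
            raise CarbonBalanceError(f"reaction {rxn.id!r}: duplicate educt labels")
        if len(set(product_labels)) != len(product_labels):
            raise CarbonBalanceError(f"reaction {rxn.id!r}: duplicate product labels")
        if sorted(educt_labels) != sorted(product_labels):
            raise CarbonBalanceError(
                f"reaction {rxn.id!r}: educt carbons {sorted(educt_labels)} do "
                f"not map onto product carbons {sorted(product_labels)}"
            )


@dataclass(frozen=True)
class TracerSpecies:
    """One purchasable isotopic species of a substrate.

    ``pattern`` holds one flag per carbon (1 = nominally 13C-labeled).
    ``purity`` is the atom% with which labeled positions actually carry 13C.
    """

    substrate: str
    label: str
    pattern: tuple[int, ...]
    purity: float = 99.0
    price: float = 0.0

    def __post_init__(self):
        if any(p not in (0, 1) for p in self.pattern):
            raise TracerSpecError(f"{self.label}: pattern entries must be 0/1")
        if not (0.0 < self.purity <= 100.0):
            raise TracerSpecError(f"{self.label}: purity must be in (0, 100]")
        if self.price < 0:
            raise TracerSpecError(f"{self.label}: negative price")


@dataclass(frozen=True)
class Mixture:
    """Per substrate, the fractional composition over its tracer species."""

    fractions: tuple[tuple[str, tuple[float, ...]], ...]

    @classmethod
    def from_dict(cls, d: dict) -> "Mixture":
        return cls(tuple((k, tuple(float(x) for x in v)) for k, v in d.items()))

    def as_dict(self) -> dict[str, tuple[float, ...]]:
        return dict(self.fractions)

    def validate(self) -> "Mixture":
        for substrate, fr in self.fractions:
            arr = np.asarray(fr, dtype=float)
            if (arr < -1e-15).any():
                raise ModelError(f"mixture for {substrate!r}: negative fraction")
            if abs(arr.sum() - 1.0) > 1e-12:
                raise ModelError(
                    f"mixture for {substrate!r}: fractions sum to {arr.sum()!r}"
                )
        return self


# ---------------------------------------------------------------------------
# FluxML-subset parsing
# ---------------------------------------------------------------------------

def _parse_linear(text: str) -> list[LinearConstraint]:
    """Parse ``'2*v1 + v2 - 0.5*v3 <= 10; v4 = 100'`` into constraints."""
    import re

    out = []
    for raw in text.split(";"):
        stmt = raw.strip()
        if not stmt:
            continue
        m = re.split(r"(<=|>=|=)", stmt)
        if len(m) != 3:
            raise ParseError(f"cannot parse constraint {stmt!r}")
        lhs, rel, rhs = (s.strip() for s in m)
        relation = {"<=": "le", ">=": "ge", "=": "eq"}[rel]
        try:
            rhs_val = float(rhs)
        except ValueError as exc:
            raise ParseError(f"constraint {stmt!r}: non-numeric rhs") from exc
        coeffs: list[tuple[str, float]] = []
        for sign, coef, flux in re.findall(
            r"([+-]?)\s*(?:(\d+\.?\d*(?:[eE][+-]?\d+)?)\s*\*?\s*)?([A-Za-z_]\w*)",
            lhs,
        ):
            c = float(coef) if coef else 1.0
            if sign == "-":
                c = -c
            coeffs.append((flux, c))
        if not coeffs:
            raise ParseError(f"constraint {stmt!r}: no flux terms")
        out.append(LinearConstraint(tuple(coeffs), relation, rhs_val))
    return out


def _format_linear(con: LinearConstraint) -> str:
    rel = {"le": "<=", "ge": ">=", "eq": "="}[con.relation]
    terms = []
    for i, (flux, c) in enumerate(con.coeffs):
        if c == 1.0:
            term = flux
        elif c == -1.0:
            term = f"-{flux}"
        else:
            term = f"{c!r}*{flux}"
        if i > 0 and not term.startswith("-"):
            term = "+ " + term
        elif i > 0:
            term = "- " + term.lstrip("-")
        terms.append(term)
    return f"{' '.join(terms)} {rel} {con.rhs!r}"


def _parse_group_spec(spec: str) -> tuple[str, tuple[int, ...], tuple[int, ...]]:
    """Parse ``'PY[1,2,3]#M0,1,2,3'`` -> (metabolite, 0-based positions, shifts)."""
    import re

    m = re.fullmatch(r"\s*(\w+)\[([\d,\s]+)\]#M([\d,\s]+)\s*", spec)
    if not m:
        raise ParseError(f"cannot parse measurement group spec {spec!r}")
    met = m.group(1)
    positions = tuple(int(p) - 1 for p in m.group(2).split(","))
    shifts = tuple(int(s) for s in m.group(3).split(","))
    return met, positions, shifts


def parse_model(document) -> NetworkModel:
    """Parse a FluxML-subset document (XML text or bytes) into a model.

    The parse is lossless for supported elements; every model invariant is
    checked (unique ids, carbon conservation, resolvable references, valid
    fragments and shifts).  Unsupported measurement types and unknown required
    elements raise :class:`ParseError` with a descriptive message.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    if root.tag != "fluxml":
        raise ParseError(f"expected <fluxml> root, got <{root.tag}>")

    network = root.find("reactionnetwork")
    if network is None:
        raise ParseError("missing <reactionnetwork>")
    pools_el = network.find("metabolitepools")
    if pools_el is None:
        raise ParseError("missing <metabolitepools>")
    metabolites = []
    for pool in pools_el.findall("pool"):
        metabolites.append(
            Metabolite(
                id=pool.get("id"),
                n_carbons=int(pool.get("atoms", "0")),
                role=pool.get("type", "intra"),
            )
        )

    reactions = []
    for rxn in network.findall("reaction"):
        educts = tuple(
            (el.get("id"), el.get("cx", "")) for el in rxn.findall("reduct")
        )
        products = tuple(
            (el.get("id"), el.get("cx", "")) for el in rxn.findall("rproduct")
        )
        reactions.append(
            Reaction(
                id=rxn.get("id"),
                educts=educts,
                products=products,
                bidirectional=rxn.get("bidirectional", "false").lower() == "true",
            )
        )

    net_cons: list[LinearConstraint] = []
    xch_cons: list[LinearConstraint] = []
    net_bounds = (-100.0, 100.0)
    xch_bounds = (0.0, 200.0)
    constraints = root.find("constraints")
    if constraints is not None:
        for tag, sink in (("net", net_cons), ("xch", xch_cons)):
            section = constraints.find(tag)
            if section is None:
                continue
            bounds_el = section.find("bounds")
            if bounds_el is not None:
                lo = float(bounds_el.get("lo"))
                hi = float(bounds_el.get("hi"))
                if tag == "net":
                    net_bounds = (lo, hi)
                else:
                    xch_bounds = (lo, hi)
            for textual in section.findall("textual"):
                sink.extend(_parse_linear(textual.text or ""))

    meas_el = root.find("measurement")
    if meas_el is None:
        raise ParseError("missing <measurement>")
    for el in meas_el:
        if el.tag not in ("mgroup", "errormodel", "rate"):
            raise ParseError(
                f"unsupported measurement element <{el.tag}> (only GC-MS "
                "mass-isotopomer groups, an affine error model, and rate "
                "measurements are supported)"
            )
    groups = []
    for g in meas_el.findall("mgroup"):
        met, positions, shifts = _parse_group_spec(g.get("spec", ""))
        groups.append(MeasurementGroup(g.get("id"), met, positions, shifts))
    err_el = meas_el.find("errormodel")
    error_model = ErrorModel(
        slope=float(err_el.get("slope")) if err_el is not None else 4.120e-2,
        intercept=float(err_el.get("intercept")) if err_el is not None else 6.655e-3,
    )
    rates = tuple(
        RateMeasurement(
            flux=r.get("flux"),
            value=float(r.get("value")),
            stddev=float(r.get("stddev")),
        )
        for r in meas_el.findall("rate")
    )

    norm_el = root.find("normalization")
    if norm_el is None:
        raise ParseError("missing <normalization> (exactly one is required)")
    normalization = Normalization(
        flux=norm_el.get("flux"),
        value=float(norm_el.get("value", "100")),
        fixed=norm_el.get("fixed", "true").lower() == "true",
    )

    model = NetworkModel(
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        net_constraints=tuple(net_cons),
        xch_constraints=tuple(xch_cons),
        net_bounds=net_bounds,
        xch_bounds=xch_bounds,
        measurement=MeasurementSpec(tuple(groups), error_model, rates),
        normalization=normalization,
        name=root.get("name", "model"),
    )
    return model.validate()


def load_model(path) -> NetworkModel:
    with open(path, "rb") as fh:
        return parse_model(fh.read())


def serialize_model(model: NetworkModel) -> str:
    """Serialize a model back to the FluxML subset (round-trip safe)."""
    root = etree.Element("fluxml", name=model.name)
    network = etree.SubElement(root, "reactionnetwork")
    pools = etree.SubElement(network, "metabolitepools")
    for met in model.metabolites:
        etree.SubElement(
            pools, "pool", id=met.id, atoms=str(met.n_carbons), type=met.role
        )
    for rxn in model.reactions:
        el = etree.SubElement(network, "reaction", id=rxn.id)
        if rxn.bidirectional:
            el.set("bidirectional", "true")
        for met, cx in rxn.educts:
            etree.SubElement(el, "reduct", id=met, cx=cx)
        for met, cx in rxn.products:
            etree.SubElement(el, "rproduct", id=met, cx=cx)
    constraints = etree.SubElement(root, "constraints")
    for tag, cons, bounds in (
        ("net", model.net_constraints, model.net_bounds),
        ("xch", model.xch_constraints, model.xch_bounds),
    ):
        section = etree.SubElement(constraints, tag)
        etree.SubElement(
            section, "bounds", lo=repr(bounds[0]), hi=repr(bounds[1])
        )
        if cons:
            textual = etree.SubElement(section, "textual")
            textual.text = "; ".join(_format_linear(c) for c in cons)
    meas = etree.SubElement(root, "measurement")
    for grp in model.measurement.groups:
        spec = "{}[{}]#M{}".format(
            grp.metabolite,
            ",".join(str(p + 1) for p in grp.positions),
            ",".join(str(s) for s in grp.shifts),
        )
        etree.SubElement(meas, "mgroup", id=grp.id, spec=spec)
    etree.SubElement(
        meas,
        "errormodel",
        slope=repr(model.measurement.error_model.slope),
        intercept=repr(model.measurement.error_model.intercept),
    )
    for rate in model.measurement.rates:
        etree.SubElement(
            meas, "rate", flux=rate.flux, value=repr(rate.value),
            stddev=repr(rate.stddev),
        )
    etree.SubElement(
        root,
        "normalization",
        flux=model.normalization.flux,
        value=repr(model.normalization.value),
        fixed="true" if model.normalization.fixed else "false",
    )
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# tracer catalogue
# ---------------------------------------------------------------------------

def parse_tracer_spec(document, model: NetworkModel | None = None):
    """Parse a tracer catalogue (YAML mapping or XML) into species per substrate.

    Returns an ordered ``dict`` mapping substrate id to its list of
    :class:`TracerSpecies`.  When ``model`` is given, substrate ids and carbon
    counts are validated against it.

    YAML form::

        GLYC:
          - {label: U-13C3, pattern: "111", purity: 99, price: 110.0}
          - {label: 12C,    pattern: "000", purity: 99, price: 0.36}

    The equivalent XML uses ``<tracers><substrate id=...><species .../></...>``.
    """
    if isinstance(document, bytes):
        document = document.decode()
    text = document.strip()
    if text.startswith("<"):
        try:
            root = etree.fromstring(text.encode())
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"malformed tracer XML: {exc}") from exc
        raw: dict[str, list[dict]] = {}
        for sub in root.findall("substrate"):
            raw[sub.get("id")] = [
                {
                    "label": sp.get("label"),
                    "pattern": sp.get("pattern"),
                    "purity": float(sp.get("purity", "99")),
                    "price": float(sp.get("price", "0")),
                }
                for sp in sub.findall("species")
            ]
    else:
        loaded = yaml.safe_load(text)
        if not isinstance(loaded, dict):
            raise ParseError("tracer YAML must be a mapping substrate -> species")
        raw = loaded

    catalogue: dict[str, list[TracerSpecies]] = {}
    model_substrates = {m.id: m for m in model.substrates} if model else None
    for substrate, entries in raw.items():
        if model_substrates is not None and substrate not in model_substrates:
            raise TracerSpecError(
                f"tracer substrate {substrate!r} is not an input pool of the model"
            )
        if not entries:
            raise TracerSpecError(f"substrate {substrate!r}: empty species list")
        species = []
        for entry in entries:
            pattern = tuple(int(ch) for ch in str(entry["pattern"]))
            if model_substrates is not None:
                n = model_substrates[substrate].n_carbons
                if len(pattern) != n:
                    raise TracerSpecError(
                        f"{substrate}/{entry.get('label')}: pattern length "
                        f"{len(pattern)} != {n} carbons"
                    )
            species.append(
                TracerSpecies(
                    substrate=substrate,
                    label=str(entry.get("label", "")),
                    pattern=pattern,
                    purity=float(entry.get("purity", 99.0)),
                    price=float(entry.get("price", 0.0)),
                )
            )
        catalogue[substrate] = species
    return catalogue


def serialize_tracer_spec(catalogue: dict[str, list[TracerSpecies]]) -> str:
    """Serialize a tracer catalogue to YAML."""
    raw = {
        substrate: [
            {
                "label": sp.label,
                "pattern": "".join(str(p) for p in sp.pattern),
                "purity": sp.purity,
                "price": sp.price,
            }
            for sp in species
        ]
        for substrate, species in catalogue.items()
    }
    return yaml.safe_dump(raw, sort_keys=False)


def species_isotopomer_distribution(
    species: TracerSpecies, background: float = 0.0
) -> np.ndarray:
    """Probability over the 2**n binary labeling states of one species.

    Positions are independent: a nominally labeled carbon is 13C with
    probability ``purity/100``, a nominally unlabeled one with probability
    ``background`` (0 by default; pass :data:`NATURAL_ABUNDANCE_13C` to model
    natural background).  State index ``i`` encodes positions left to right,
    i.e. bit ``n-1-k`` of ``i`` is carbon ``k``.
    """
    n = len(species.pattern)
    p_label = np.where(
        np.asarray(species.pattern, dtype=bool), species.purity / 100.0, background
    )
    dist = np.ones(1)
    for k in range(n):
        dist = np.concatenate([dist * (1.0 - p_label[k]), dist * p_label[k]])
        # after processing carbon k, the high bit corresponds to carbon k
    # reorder so that carbon 0 is the most significant bit
    out = np.zeros(2**n)
    for state in range(2**n):
        # state built above: bit k (from LSB) = carbon k; convert to MSB-first
        msb_state = 0
        for k in range(n):
            if state >> k & 1:
                msb_state |= 1 << (n - 1 - k)
        out[msb_state] = dist[state]
    return out


def substrate_isotopomer_distribution(
    species_list: list[TracerSpecies],
    fractions,
    background: float = 0.0,
) -> np.ndarray:
    """Mixture-weighted isotopomer distribution of one substrate pool."""
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(species_list):
        raise ModelError("fraction vector length does not match species count")
    dists = [species_isotopomer_distribution(sp, background) for sp in species_list]
    return np.tensordot(fractions, np.array(dists), axes=1)
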