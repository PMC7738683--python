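"""Cortical parcellation and white-matter tract metadata.

The volume and connectivity analyses operate on a 100-parcel cortical atlas in
which every parcel belongs to exactly one of seven canonical large-scale
networks (Visual, SomMot, DorsalAttn, Salience, Limbic, Control, Default); the
tract analyses operate on the 48-tract JHU ICBM-DTI-81 white-matter catalog.

The bundled parcel table ``schaefer100_7networks_synthetic.tsv`` is a synthetic
stand-in for the public Schaefer/Yeo 100-parcel 7-network release: it keeps the
release's conventions (network-grouped ordering inside each hemisphere block,
``7Networks_<hemi>_<network>_<k>`` naming, hemisphere-symmetric counts, the
Default network largest) but the exact region counts and names are not the
published lookup table.  Region indices are 0-based everywhere internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import pandas as pd

__all__ = [
    "NETWORK_NAMES",
    "RegionRecord",
    "Atlas",
    "TractCatalog",
    "load_atlas",
    "load_tract_catalog",
    "AtlasError",
]

#: Canonical network order; fixes network indices and all ranking tie-breaks.
NETWORK_NAMES: tuple[str, ...] = (
    "Visual",
    "SomMot",
    "DorsalAttn",
    "Salience",
    "Limbic",
    "Control",
    "Default",
)

_HEMISPHERES = ("left", "right")


class AtlasError(ValueError):
    """Raised for malformed atlas or tract-catalog files."""


@dataclass(frozen=True)
class RegionRecord:
    """One cortical parcel: 0-based index, label, hemisphere, network name."""

    index: int
    name: str
    hemisphere: str
    network: str


@dataclass(frozen=True)
class Atlas:
    """Parcellation with a region -> network assignment.

    ``region_to_network[r]`` is the index into :attr:`networks` of region
    ``r``'s network; region order is file order and is fixed.
    """

    regions: tuple[RegionRecord, ...]
    networks: tuple[str, ...] = NETWORK_NAMES

    region_to_network: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        lookup = {n: i for i, n in enumerate(self.networks)}
        object.__setattr__(
            self,
            "region_to_network",
            tuple(lookup[r.network] for r in self.regions),
        )
        counts = self.network_sizes
        for name, c in zip(self.networks, counts):
            if c == 0:
                raise AtlasError(f"network {name!r} has no regions")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def n_edges(self) -> int:
        """Number of lower-triangle region pairs, R(R-1)/2."""
        r = self.n_regions
        return r * (r - 1) // 2

    @property
    def network_sizes(self) -> tuple[int, ...]:
        counts = [0] * self.n_networks
        for k in self.region_to_network:
            counts[k] += 1
        return tuple(counts)

    def regions_in_network(self, network_index: int) -> list[int]:
        return [
            r for r, k in enumerate(self.region_to_network) if k == network_index
        ]


@dataclass(frozen=True)
class TractCatalog:
    """Ordered catalog of white-matter tract names (48 in the JHU atlas)."""

    tracts: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tracts) == 0:
            raise AtlasError("tract catalog is empty")
        if len(set(self.tracts)) != len(self.tracts):
            dupes = sorted(
                {t for t in self.tracts if list(self.tracts).count(t) > 1}
            )
            raise AtlasError(f"duplicate tract names: {dupes}")

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    def index_of(self, name: str) -> int:
        return self.tracts.index(name)


def _bundled(name: str) -> Path:
    return Path(str(resources.files("lonebrain").joinpath("data", name)))


def load_atlas(
    path: str | Path = "bundled",
    *,
    allow_nonstandard_size: bool = False,
) -> Atlas:
    """Load a parcellation table (columns: index, name, hemisphere, network).

    ``path="bundled"`` loads the packaged synthetic stand-in table (100
    regions / 7 networks).  A region count other than 100 is rejected unless
    ``allow_nonstandard_size`` is set (reduced test atlases).
    """
    if path == "bundled":
        path = _bundled("schaefer100_7networks_synthetic.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"index": int, "name": str})
    required = {"index", "name", "hemisphere", "network"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"atlas file missing columns: {sorted(missing)}")

    bad_net = sorted(set(df["network"]) - set(NETWORK_NAMES))
    if bad_net:
        raise AtlasError(
            f"unknown network name(s) {bad_net}; expected one of {list(NETWORK_NAMES)}"
        )
    bad_hemi = sorted(set(df["hemisphere"]) - set(_HEMISPHERES))
    if bad_hemi:
        raise AtlasError(f"unknown hemisphere label(s) {bad_hemi}")

    n = len(df)
    if n != 100 and not allow_nonstandard_size:
        raise AtlasError(
            f"expected 100 regions, found {n}; pass allow_nonstandard_size=True "
            "for reduced test atlases"
        )
    if sorted(df["index"]) != list(range(n)):
        raise AtlasError("region indices must be exactly 0..n-1 and unique")

    df = df.sort_values("index")
    regions = tuple(
        RegionRecord(int(r.index), r.name, r.hemisphere, r.network)
        for r in df.itertuples()
    )
    networks = tuple(n for n in NETWORK_NAMES if n in set(df["network"]))
    if not allow_nonstandard_size:
        networks = NETWORK_NAMES
    return Atlas(regions=regions, networks=networks)


def load_tract_catalog(path: str | Path = "bundled") -> TractCatalog:
    """Load a one-column tract-name table; bundled default is the 48-tract JHU list."""
    if path == "bundled":
        path = _bundled("jhu48_tracts.tsv")
    df = pd.read_csv(path, sep="\t")
    if "tract" not in df.columns:
        raise AtlasError("tract catalog must have a 'tract' column")
    if len(df) == 0:
        raise AtlasError("tract catalog is empty")
    return TractCatalog(tracts=tuple(df["tract"].astype(str)))
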