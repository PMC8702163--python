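import pytest

from detectcomp.study_table import ComparisonTable, MethodCount
from detectcomp.synthetic_data import SimulationConfig, generate_table

_TAXA = {
    "Martes americana": ("Carnivora", "Mustelidae", "Martes"),
    "Lynx rufus": ("Carnivora", "Felidae", "Lynx"),
    "Meles meles": ("Carnivora", "Mustelidae", "Meles"),
    "Sciurus niger": ("Rodentia", "Sciuridae", "Sciurus"),
}


def rec(pid, method, n, species="Martes americana", realm="nearctic",
        area=10.0, mass=1.0, camera_analysis=None, tissue=None):
    """Shorthand MethodCount with sensible defaults for unit tests."""
    order, family, genus = _TAXA[species]
    if camera_analysis is None:
        camera_analysis = "spatial" if method == "camera" else "none"
    if tissue is None:
        tissue = "hair" if method == "genetic" else "none"
    return MethodCount(
        population_id=pid, order=order, family=family, genus=genus,
        species=species, realm=realm, method=method, n_individuals=float(n),
        site_area_km2=area, body_mass_kg=mass,
        camera_analysis=camera_analysis, tissue=tissue,
    )


def table(*records):
    return ComparisonTable.from_records(records)


@pytest.fixture
def tiny_table():
    """Two populations, each observed by live trapping and one other method."""
    return table(
        rec("p1", "live_trap", 10, species="Martes americana"),
        rec("p1", "camera", 12, species="Martes americana"),
        rec("p2", "live_trap", 30, species="Lynx rufus"),
        rec("p2", "genetic", 33, species="Lynx rufus"),
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """One draw of the default synthetic study compilation."""
    return generate_table(SimulationConfig(seed=20210))
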