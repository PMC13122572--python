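import pytest

from gilltep.water_chem import WaterComposition


@pytest.fixture
def inpa_water() -> WaterComposition:
    """Reference ion-poor acclimation water (measured chemistry)."""
    return WaterComposition(
        name="INPA",
        ph=7.0,
        doc_mg_l=0.59,
        dic_mg_l=0.30,
        ions={"Na": 63.0, "Ca": 5.0, "K": 12.0, "Mg": 1.0, "Cl": 11.0},
        conductivity_us_cm=17.0,
        temperature=27.0,
    )


@pytest.fixture
def rio_negro_water() -> WaterComposition:
    return WaterComposition(
        name="Rio Negro",
        ph=4.0,
        doc_mg_l=11.2,
        dic_mg_l=0.21,
        ions={"Na": 12.0, "Ca": 8.0, "K": 6.0, "Mg": 3.0, "Cl": 10.0},
        conductivity_us_cm=11.0,
        temperature=27.0,
    )


@pytest.fixture
def plasma_mmol() -> dict[str, float]:
    """Assumed plasma: measured species Na, generic teleost Cl."""
    return {"Na": 158.0, "Cl": 130.0}
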