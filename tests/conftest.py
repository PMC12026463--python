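import json

import pytest

from supplyscore.fixtures import table13_fixture, vodka_example


@pytest.fixture(scope="session")
def table13():
    return table13_fixture()


@pytest.fixture(scope="session")
def vodka():
    return vodka_example()


@pytest.fixture
def uk_supplier_file(tmp_path):
    """A minimal UK spirits supplier record on disk (no audit data)."""
    path = tmp_path / "uk_vodka.json"
    path.write_text(
        json.dumps(
            {
                "supplier_id": "UK-VODKA-01",
                "country": "United Kingdom",
                "commodity": "vodka",
                "economics": {"lpi": 3.7, "gdp_per_capita": 49463.9, "gdp_growth": 0.3},
            }
        )
    )
    return path


@pytest.fixture
def incident_csv(tmp_path):
    """Incident log: one fraud notification for vodka plus unrelated incidents."""
    path = tmp_path / "incidents.csv"
    rows = [
        "date,commodity,incident_category,signal_category,notification_reason,health_risk,matrix_relevant",
        "2024-09-15,vodka,fraud,compliance,exceeded_limit,very_serious,true",
        "2024-08-01,cheese,control,,,,",
        "2024-07-10,onions,outbreak,safety,exceeded_limit,serious,true",
        "2023-01-01,vodka,recall,,,,",  # outside a 2024-12-31 window
    ]
    path.write_text("\n".join(rows) + "\n")
    return path
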