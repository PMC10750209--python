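"""Catalog of the commercial SPION products used by the platform studies.

Core sizes are quoted as ranges by the vendor; the catalog stores the range
and uses its midpoint as the median of a log-normal number distribution
(shape 0.1).  Stock concentrations in mg(Fe)/mL.  Saturation magnetization
and anisotropy are effective model parameters, not vendor data.
"""

from __future__ import annotations

import csv
import io

from .particles import ParticleSpec

__all__ = ["CATALOG", "get_particle", "catalog_table"]


def _entry(key, core_range, d_h, coating, surface, code, stock):
    mid = 0.5 * (core_range[0] + core_range[1])
    return key, ParticleSpec(
        name=key,
        core_diameter=mid,
        core_range=core_range,
        hydrodynamic_diameter=d_h,
        coating=coating,
        surface=surface,
        product_code=code,
        stock_concentration=stock,
    )


CATALOG: dict[str, ParticleSpec] = dict([
    _entry("synomag-D-50", (20, 25), 50, "dextran", "plain", "104-00-501", 10.0),
    _entry("synomag-D-70", (30, 35), 70, "dextran", "plain", "104-00-701", 10.0),
    _entry("synomag-S-90", (30, 35), 90, "starch", "plain", "105-00-701", 10.0),
    _entry("synomag-CLD-redF", (20, 25), 50, "dextran", "plain", "125-00-501", 3.0),
    _entry("nanomag-D-spio-20", (5, 10), 20, "dextran", "plain", "79-00-201", 2.4),
    _entry("nanomag-D-spio-50", (5, 10), 50, "dextran", "plain", "79-00-501", 2.4),
    _entry("nanomag-D-spio-100", (10, 15), 100, "dextran", "plain", "79-00-102", 2.4),
    _entry("perimag-plain", (5, 10), 130, "dextran", "plain", "102-00-132", 8.5),
    _entry("perimag-COOH", (5, 10), 130, "dextran", "COOH", "102-02-132", 5.0),
    _entry("BNF-Dextran", (15, 20), 100, "dextran", "plain", "84-00-102", 10.0),
])


def get_particle(key: str) -> ParticleSpec:
    """Look up a catalog entry by name or product code."""
    if key in CATALOG:
        return CATALOG[key]
    for p in CATALOG.values():
        if p.product_code == key:
            return p
    raise KeyError(f"unknown particle {key!r}; known: {sorted(CATALOG)}")


def catalog_table() -> str:
    """CSV rendering of the catalog."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["name", "core_diameter_nm", "core_range_nm", "hydrodynamic_diameter_nm",
                "coating", "surface", "product_code", "stock_concentration_mgFe_per_mL"])
    for p in CATALOG.values():
        w.writerow([p.name, p.core_diameter, f"{p.core_range[0]}-{p.core_range[1]}",
                    p.hydrodynamic_diameter, p.coating, p.surface, p.product_code,
                    p.stock_concentration])
    return buf.getvalue()
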