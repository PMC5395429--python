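"""Shared fixtures: small analytic ocean fields and genotype datasets."""

import datetime

import numpy as np
import pytest

from seaconn.field_model import GridSpec, OceanField
from seaconn.popgen import GenotypeDataset


def make_constant_field(u=0.0, v=0.0, temp=15.0, n_days=10,
                        depth_levels=(1.0, 5.0, 10.0), d=0.05,
                        lon_min=17.0, lon_max=19.0, lat_min=39.0, lat_max=41.0,
                        year=2005):
    grid = GridSpec(lon_min=lon_min, lon_max=lon_max, lat_min=lat_min,
                    lat_max=lat_max, d_lon=d, d_lat=d,
                    depth_levels=depth_levels,
                    time_origin=datetime.date(year, 1, 1), n_days=n_days)
    return OceanField(grid,
                      np.full(grid.shape, float(u)),
                      np.full(grid.shape, float(v)),
                      np.full(grid.shape, float(temp)))


@pytest.fixture
def still_field():
    """Quiescent 15 degC basin (no currents, no mortality)."""
    return make_constant_field()


@pytest.fixture
def still_field_year():
    """Quiescent cold basin covering a full calendar year."""
    return make_constant_field(n_days=365)


@pytest.fixture
def warm_field_year():
    """Quiescent 20 degC basin (above the 18 degC gate) for a full year."""
    return make_constant_field(temp=20.0, n_days=365)


def simple_dataset(genotypes, pop_labels, snp_locus=None, snp_pos=None):
    """Build a GenotypeDataset from a genotype matrix with minimal metadata."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_snp = g.shape
    snp_locus = np.arange(n_snp) if snp_locus is None else np.asarray(snp_locus)
    snp_pos = np.ones(n_snp, dtype=int) if snp_pos is None else np.asarray(snp_pos)
    n_loci = int(snp_locus.max()) + 1
    return GenotypeDataset(
        genotypes=g, snp_locus=snp_locus, snp_pos=snp_pos,
        locus_names=[f"L{k}" for k in range(n_loci)],
        individual_names=[f"i{k}" for k in range(n_ind)],
        pop_labels=list(pop_labels),
    )
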