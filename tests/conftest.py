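import numpy as np
import pytest

from phenostate.inventory import Fate, Phenology, PlotRecord, TreeRecord


def make_tree(i, plot_id="p1", species="sp1", pheno=Phenology.EV,
              dbh_prev=20.0, dbh_curr=21.0, fate=Fate.SURVIVOR):
    return TreeRecord(tree_id=f"t{i}", plot_id=plot_id, species_id=species,
                      phenology=pheno, dbh_prev=dbh_prev, dbh_curr=dbh_curr,
                      fate=fate)


def make_plot(plot_id, trees, **kw):
    defaults = dict(lon=-80.0, lat=40.0, area=0.1, interval=5.0,
                    env_pcs=np.zeros(10), mat=10.0)
    defaults.update(kw)
    return PlotRecord(plot_id=plot_id, trees=trees, **defaults)


def _uniform_trees(n, plot_id, pheno=Phenology.EV, species="sp1", dead=0,
                   dbh=20.0, species_cycle=None):
    trees = []
    for i in range(n):
        sp = species if species_cycle is None else species_cycle[i % len(species_cycle)]
        if i < dead:
            trees.append(TreeRecord(f"{plot_id}t{i}", plot_id, sp, pheno,
                                    dbh_prev=dbh, dbh_curr=None, fate=Fate.DIED))
        else:
            trees.append(TreeRecord(f"{plot_id}t{i}", plot_id, sp, pheno,
                                    dbh_prev=dbh, dbh_curr=dbh + 1, fate=Fate.SURVIVOR))
    return trees


@pytest.fixture(scope="session")
def toy_eight_plots():
    """Eight hand-constructed plots; exactly three survive the filters.

    1: 12 mixed-species trees          -> kept
    2: 9 trees                         -> min_trees
    3: 15 trees, 9 dead (60%)          -> mortality
    4: 20 trees, one species           -> min_species
    5: 11 mixed trees                  -> kept
    6: 30 trees, one species 95% of BA -> single_species_ba
    7: 14 mixed trees                  -> kept
    8: 10 trees, 20% of BA UNKNOWN     -> unknown_ba
    """
    cyc = ["A", "B", "C"]
    plots = [
        make_plot("p1", _uniform_trees(12, "p1", species_cycle=cyc)),
        make_plot("p2", _uniform_trees(9, "p2", species_cycle=cyc)),
        make_plot("p3", _uniform_trees(15, "p3", dead=9, species_cycle=cyc)),
        make_plot("p4", _uniform_trees(20, "p4", species="mono")),
        make_plot("p5", _uniform_trees(11, "p5", species_cycle=cyc)),
    ]
    # plot 6: 29 equal trees of one species plus one tiny tree of another:
    # the dominant species holds ~99% of basal area
    t6 = _uniform_trees(29, "p6", species="big")
    t6.append(TreeRecord("p6t29", "p6", "small", Phenology.EV,
                         dbh_prev=4.0, dbh_curr=5.0, fate=Fate.SURVIVOR))
    plots.append(make_plot("p6", t6))
    plots.append(make_plot("p7", _uniform_trees(14, "p7", species_cycle=cyc)))
    # plot 8: 8 known + 2 unknown of equal size -> 20% of BA unknown
    t8 = _uniform_trees(8, "p8", species_cycle=cyc)
    for i in (8, 9):
        t8.append(TreeRecord(f"p8t{i}", "p8", "D", Phenology.UNKNOWN,
                             dbh_prev=20.0, dbh_curr=21.0, fate=Fate.SURVIVOR))
    plots.append(make_plot("p8", t8))
    return plots


@pytest.fixture(scope="session")
def recovery_inventory():
    """One mid-sized synthetic inventory with the default planted feedbacks."""
    from phenostate import GeneratorParams, generate_environment, \
        generate_two_census_inventory

    params = GeneratorParams(n_plots=1500, seed=424242)
    plots = generate_two_census_inventory(generate_environment(params), params)
    return params, plots
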