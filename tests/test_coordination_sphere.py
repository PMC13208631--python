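"""Structure parsing, metal-site location and sphere profiling."""

import math

import numpy as np
import pytest

from geocofactor.coordination_sphere import (
    AA_ORDER,
    AA_THREE_TO_ONE,
    MetalSite,
    StructureAtom,
    StructureModel,
    StructureParseError,
    StructureResidue,
    find_metal_sites,
    frequency_vector,
    hydropathy_stats,
    parse_structure,
    profile_site,
    profile_structures,
    sphere_residues,
)
from geocofactor.fixtures import SphereSpec, make_structure


def _pdb_line(record, serial, name, resname, chain, seq, xyz, element,
              altloc=" ", occ=1.0):
    field = name.ljust(4) if len(element) == 2 else (" " + name).ljust(4)
    return (
        f"{record:<6s}{serial:>5d} {field}{altloc}{resname:>3s} {chain}"
        f"{seq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def oracle_sphere(model, site, cutoff, aliases):
    """Exhaustive all-atom-pairs distance scan."""
    hits = []
    for res in model.residues:
        if res.hetero:
            continue
        if res.name not in AA_THREE_TO_ONE and res.name not in aliases:
            continue
        dmin = min(
            math.dist(a.coord, b.coord)
            for a in res.atoms
            for b in site.ligand_atoms
        )
        if dmin <= cutoff:
            hits.append((res.chain, res.serial))
    return hits


@pytest.fixture
def sf4_structure(tmp_path):
    spec = SphereSpec(
        ligand_code="SF4",
        placements=(("CYS", 2.3), ("CYS", 2.4), ("HIS", 3.5), ("ALA", 6.0)),
        seed=11,
        structure_id="SF4FIX",
    )
    path, truth = make_structure(spec, tmp_path)
    return path, truth


class TestParseStructure:
    def test_fixture_round_trip(self, sf4_structure):
        path, _ = sf4_structure
        model = parse_structure(path)
        assert len(model.residues) == 5  # 4 amino acids + the SF4 ligand
        assert sum(r.hetero for r in model.residues) == 1
        assert model.n_atoms == 4 * 5 + 8

    def test_waters_only_has_no_standard_residues(self, tmp_path):
        lines = [
            _pdb_line("HETATM", i + 1, "O", "HOH", "A", i + 1,
                      (float(i), 0.0, 0.0), "O")
            for i in range(3)
        ] + ["END"]
        path = tmp_path / "waters.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = parse_structure(path)
        assert all(r.hetero for r in model.residues)

    def test_first_model_only(self, tmp_path):
        lines = (
            ["MODEL        1",
             _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C"),
             "ENDMDL",
             "MODEL        2",
             _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, (9.0, 9.0, 9.0), "C"),
             _pdb_line("ATOM", 2, "CA", "GLY", "A", 2, (5.0, 5.0, 5.0), "C"),
             "ENDMDL", "END"]
        )
        path = tmp_path / "two_models.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = parse_structure(path)
        assert len(model.residues) == 1
        assert model.residues[0].atoms[0].coord == (0.0, 0.0, 0.0)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C",
                      altloc="A", occ=0.4),
            _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, (3.0, 0.0, 0.0), "C",
                      altloc="B", occ=0.6),
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = parse_structure(path)
        assert len(model.residues[0].atoms) == 1
        assert model.residues[0].atoms[0].coord == (3.0, 0.0, 0.0)

    def test_missing_and_empty_files_rejected(self, tmp_path):
        with pytest.raises(StructureParseError, match="unreadable or empty"):
            parse_structure(tmp_path / "nope.pdb")
        empty = tmp_path / "empty.pdb"
        empty.write_text("")
        with pytest.raises(StructureParseError):
            parse_structure(empty)


class TestFindMetalSites:
    def test_single_hem_site(self, tmp_path, registry):
        spec = SphereSpec("HEM", (("HIS", 2.5),), seed=1, structure_id="H")
        path, _ = make_structure(spec, tmp_path)
        sites = find_metal_sites(parse_structure(path), registry)
        assert len(sites) == 1
        assert registry[sites[0].ligand_code].metal_class == "Fe"

    def test_sf4_and_nfu_two_sites(self, tmp_path, registry):
        # two files merged by hand into one two-ligand model
        p1, _ = make_structure(
            SphereSpec("SF4", (("CYS", 2.3),), seed=1, structure_id="A"), tmp_path
        )
        p2, _ = make_structure(
            SphereSpec("NFU", (("CYS", 2.3),), seed=2, structure_id="B"), tmp_path
        )
        m1, m2 = parse_structure(p1), parse_structure(p2)
        shifted = [
            StructureResidue(
                chain="B",
                serial=r.serial + 100,
                name=r.name,
                hetero=r.hetero,
                atoms=tuple(
                    StructureAtom(a.name, a.element,
                                  (a.coord[0] + 50, a.coord[1], a.coord[2]))
                    for a in r.atoms
                ),
            )
            for r in m2.residues
        ]
        model = StructureModel("AB", m1.residues + tuple(shifted))
        sites = find_metal_sites(model, registry)
        codes = {s.ligand_code for s in sites}
        assert codes == {"SF4", "NFU"}
        classes = {registry[s.ligand_code].metal_class for s in sites}
        assert classes == {"Fe", "FeNi"}

    def test_unregistered_ligand_ignored(self, tmp_path, registry):
        lines = [
            _pdb_line("HETATM", 1, "ZN", "ZN", "A", 1, (0.0, 0.0, 0.0), "ZN"),
            _pdb_line("ATOM", 2, "CA", "ALA", "A", 2, (2.0, 0.0, 0.0), "C"),
            "END",
        ]
        path = tmp_path / "zn.pdb"
        path.write_text("\n".join(lines) + "\n")
        assert find_metal_sites(parse_structure(path), registry) == []


class TestSphereResidues:
    def test_known_distances(self, sf4_structure, aliases):
        path, truth = sf4_structure
        model = parse_structure(path)
        (site,) = find_metal_sites(model)
        names = [r.name for r in sphere_residues(model, site, 5.0)]
        assert names == ["CYS", "CYS", "HIS"]  # ALA at 6.0 Å excluded

    def test_matches_exhaustive_scan_on_random_fixtures(self, tmp_path, aliases, rng):
        types = list(AA_THREE_TO_ONE)
        for k in range(25):
            placements = tuple(
                (types[int(rng.integers(len(types)))],
                 float(rng.uniform(2.2, 9.0)))
                for _ in range(int(rng.integers(3, 10)))
            )
            spec = SphereSpec("SF4", placements, seed=int(rng.integers(2**31)),
                              structure_id=f"R{k}")
            path, _ = make_structure(spec, tmp_path)
            model = parse_structure(path)
            (site,) = find_metal_sites(model)
            for cutoff in (3.0, 5.0, 8.0):
                got = [(r.chain, r.serial)
                       for r in sphere_residues(model, site, cutoff)]
                assert got == oracle_sphere(model, site, cutoff, aliases)

    def test_cutoff_monotonicity(self, sf4_structure):
        path, _ = sf4_structure
        model = parse_structure(path)
        (site,) = find_metal_sites(model)
        prev: set = set()
        for cutoff in (3.0, 5.0, 8.0):
            now = {(r.chain, r.serial) for r in sphere_residues(model, site, cutoff)}
            assert prev <= now
            prev = now

    def test_unknown_site_rejected(self, sf4_structure):
        path, _ = sf4_structure
        model = parse_structure(path)
        bogus = MetalSite("X", "HEM", "Z", 999,
                          (StructureAtom("FE", "FE", (0.0, 0.0, 0.0)),))
        with pytest.raises(ValueError, match="not found"):
            sphere_residues(model, bogus)

    def test_metal_atoms_only_is_a_subset(self, sf4_structure):
        path, _ = sf4_structure
        model = parse_structure(path)
        (site,) = find_metal_sites(model)
        all_atoms = {r.serial for r in sphere_residues(model, site, 5.0)}
        metal_only = {r.serial
                      for r in sphere_residues(model, site, 5.0,
                                               metal_atoms_only=True)}
        assert metal_only <= all_atoms


class TestHydropathyStats:
    def test_identical_cysteines(self, kd_scale):
        assert hydropathy_stats(["CYS", "CYS"], kd_scale) == (2.5, 0.0)

    def test_singleton_sd_zero(self, kd_scale):
        mean, sd = hydropathy_stats(["ILE"], kd_scale)
        assert (mean, sd) == (4.5, 0.0)

    def test_matches_direct_formula(self, kd_scale, rng):
        names = [list(AA_THREE_TO_ONE)[i]
                 for i in rng.integers(0, 20, size=6)]
        mean, sd = hydropathy_stats(names, kd_scale)
        vals = np.array([kd_scale[n] for n in names])
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=1))

    def test_empty_list_flagged_not_crashed(self, kd_scale):
        mean, sd = hydropathy_stats([], kd_scale)
        assert math.isnan(mean) and math.isnan(sd)

    def test_alias_mapped_to_parent(self, kd_scale):
        assert hydropathy_stats(["MSE"], kd_scale) == hydropathy_stats(
            ["MET"], kd_scale
        )


class TestFrequencyVector:
    def test_half_cys_half_his(self):
        vec = frequency_vector(["CYS", "CYS", "HIS", "HIS"])
        assert vec[AA_ORDER.index("C")] == 0.5
        assert vec[AA_ORDER.index("H")] == 0.5
        assert vec.sum() == pytest.approx(1.0)

    def test_uniform_over_all_twenty(self):
        vec = frequency_vector(list(AA_THREE_TO_ONE))
        assert np.allclose(vec, 0.05)

    def test_permutation_equivariance(self, rng):
        names = [list(AA_THREE_TO_ONE)[i] for i in rng.integers(0, 20, size=15)]
        shuffled = list(names)
        rng.shuffle(shuffled)
        assert np.array_equal(frequency_vector(names), frequency_vector(shuffled))

    def test_sums_to_one_and_counts(self, rng):
        names = [list(AA_THREE_TO_ONE)[i] for i in rng.integers(0, 20, size=30)]
        vec = frequency_vector(names)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
        idx = AA_ORDER.index("C")
        assert vec[idx] == names.count("CYS") / 30


def _rigid_transform(model, site, rotation, translation):
    def move(atom):
        new = rotation @ np.array(atom.coord) + translation
        return StructureAtom(atom.name, atom.element, tuple(float(c) for c in new))

    residues = tuple(
        StructureResidue(r.chain, r.serial, r.name, r.hetero,
                         tuple(move(a) for a in r.atoms))
        for r in model.residues
    )
    new_model = StructureModel(model.structure_id, residues)
    new_site = MetalSite(site.structure_id, site.ligand_code, site.chain,
                         site.serial, tuple(move(a) for a in site.ligand_atoms))
    return new_model, new_site


def test_profile_invariant_under_rigid_motion(sf4_structure, rng):
    path, _ = sf4_structure
    model = parse_structure(path)
    (site,) = find_metal_sites(model)
    before = profile_site(model, site)
    # random rotation via QR decomposition
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved_model, moved_site = _rigid_transform(model, site, q, np.array([10., -4., 7.]))
    after = profile_site(moved_model, moved_site)
    assert [r.serial for r in before.nearby_residues] == [
        r.serial for r in after.nearby_residues
    ]
    assert before.freq_vector == after.freq_vector
    assert before.hydropathy_mean == pytest.approx(after.hydropathy_mean)
    assert before.hydropathy_sd == pytest.approx(after.hydropathy_sd)


def test_profile_structures_batch_layout(tmp_path):
    p1, _ = make_structure(
        SphereSpec("SF4", (("CYS", 2.3), ("CYS", 2.5)), seed=1, structure_id="S1"),
        tmp_path,
    )
    p2, _ = make_structure(
        SphereSpec("F43", (("HIS", 2.5),), seed=2, structure_id="S2"), tmp_path
    )
    df = profile_structures([p1, p2])
    assert list(df["metal_class"]) == ["Fe", "Ni"]
    assert list(df["n_residues"]) == [2, 1]
    freq_cols = [f"freq_{aa}" for aa in AA_ORDER]
    assert np.allclose(df[freq_cols].sum(axis=1), 1.0)


def test_profile_structures_skips_bad_file(tmp_path):
    good, _ = make_structure(
        SphereSpec("SF4", (("CYS", 2.3),), seed=1, structure_id="G"), tmp_path
    )
    bad = tmp_path / "bad.pdb"
    bad.write_text("")
    with pytest.warns(UserWarning, match="skipping"):
        df = profile_structures([bad, good])
    assert list(df["structure_id"]) == ["G"]
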