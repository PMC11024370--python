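"""Genotype matrix, target-specific selection and difference rate.

The brute-force oracles here re-derive every selection directly from the VCF
text (or the truth manifest), independently of the matrix implementation.
"""

import numpy as np
import pytest

from selfscan.vcf_compare import (
    Genotype,
    VcfOrderError,
    load_matrix,
    pairwise_difference_rate,
    similarity_table,
    target_specific,
)
from selfscan.vcfio import write_vcf

REF_LENGTH = 1_000_000


def write_panel_vcf(path, samples, rows):
    write_vcf(str(path), {"chr1": REF_LENGTH}, samples, rows)
    return path


# --- independent per-site scan over the raw VCF text ----------------------


def brute_force_target_specific(vcf_path, targets, comparators):
    samples = []
    hits = []
    for line in open(vcf_path):
        if line.startswith("##"):
            continue
        fields = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            samples = fields[9:]
            continue
        chrom, pos, ref, alts = fields[0], int(fields[1]), fields[3], fields[4].split(",")
        gts = dict(zip(samples, (f.split(":")[0] for f in fields[9:])))
        for k, alt in enumerate(alts, start=1):
            def status(gt):
                alleles = gt.replace("|", "/").split("/")
                if "." in alleles:
                    return "missing"
                copies = sum(a == str(k) for a in alleles)
                if copies == len(alleles):
                    return "hom_alt"
                return "het" if copies else "hom_ref"

            if all(status(gts[t]) == "hom_alt" for t in targets) and all(
                status(gts[c]) == "hom_ref" for c in comparators
            ):
                hits.append((chrom, pos, ref, alt))
    return hits


@pytest.fixture
def six_site_vcf(tmp_path):
    """6 sites x 4 accessions covering hom/het/missing/multi-allelic cases."""
    samples = ["mutA", "mutB", "wt1", "wt2"]
    rows = [
        ("chr1", 100, "A", ["G"], ["1/1", "1/1", "0/0", "0/0"], None),  # specific
        ("chr1", 200, "C", ["T"], ["1/1", "0/1", "0/0", "0/0"], None),  # het target
        ("chr1", 300, "G", ["A"], ["1/1", "1/1", "0/0", "./."], None),  # missing comp
        ("chr1", 400, "T", ["C"], ["0/0", "0/0", "0/0", "0/0"], None),  # invariant
        ("chr1", 500, "A", ["C", "T"], ["2/2", "2/2", "0/0", "0/0"], None),  # multi-allelic
        ("chr1", 600, "G", ["C"], ["1/1", "1/1", "1/1", "1/1"], None),  # shared by all
    ]
    path = write_panel_vcf(tmp_path / "six.vcf", samples, rows)
    return path, samples


class TestLoadMatrix:
    def test_empty_vcf_gives_empty_matrix(self, tmp_path):
        path = write_panel_vcf(tmp_path / "empty.vcf", ["a", "b"], [])
        matrix = load_matrix(path, REF_LENGTH)
        assert len(matrix) == 0
        assert matrix.samples == ["a", "b"]

    def test_multiallelic_split_recodes_each_row(self, tmp_path):
        rows = [("chr1", 500, "A", ["C", "T"], ["2/2", "1/2", "0/0", "./."], None)]
        path = write_panel_vcf(tmp_path / "ma.vcf", ["s1", "s2", "s3", "s4"], rows)
        matrix = load_matrix(path, REF_LENGTH)
        assert [(r.ref, r.alt) for r in matrix.records] == [("A", "C"), ("A", "T")]
        row_c, row_t = matrix.calls
        # 2/2 carries no copy of C but two of T
        assert Genotype(row_c[0]) == Genotype.HOM_REF
        assert Genotype(row_t[0]) == Genotype.HOM_ALT
        # 1/2 is het on both split rows
        assert Genotype(row_c[1]) == Genotype.HET
        assert Genotype(row_t[1]) == Genotype.HET
        assert Genotype(row_c[3]) == Genotype.MISSING

    def test_unsorted_input_names_offending_record(self, tmp_path):
        rows = [
            ("chr1", 500, "A", ["T"], ["0/0"], None),
            ("chr1", 100, "C", ["G"], ["0/0"], None),
        ]
        path = write_panel_vcf(tmp_path / "unsorted.vcf", ["s1"], rows)
        with pytest.raises(VcfOrderError, match="chr1:100"):
            load_matrix(path, REF_LENGTH)

    def test_vcf_without_gt_rejected(self, tmp_path):
        path = tmp_path / "nogt.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t5\t.\tA\tT\t.\tPASS\tDP=3\n"
        )
        with pytest.raises(ValueError, match="GT"):
            load_matrix(path, REF_LENGTH)

    def test_record_count_matches_truth_manifest(self, demo_dataset):
        matrix = load_matrix(
            demo_dataset["paths"]["vcf"], demo_dataset["manifest"]["reference"]["length"]
        )
        assert len(matrix) == demo_dataset["manifest"]["n_records"]


class TestTargetSpecific:
    def test_all_identical_sites_select_nothing(self, tmp_path):
        rows = [
            ("chr1", 10, "A", ["T"], ["1/1", "1/1"], None),
            ("chr1", 20, "C", ["G"], ["0/0", "0/0"], None),
        ]
        path = write_panel_vcf(tmp_path / "same.vcf", ["a", "b"], rows)
        matrix = load_matrix(path, REF_LENGTH)
        assert len(target_specific(matrix, ["a"], ["b"])) == 0

    def test_six_site_fixture_matches_brute_force(self, six_site_vcf):
        path, _ = six_site_vcf
        matrix = load_matrix(path, REF_LENGTH)
        selection = target_specific(matrix, ["mutA", "mutB"], ["wt1", "wt2"])
        got = [(r.chrom, r.pos, r.ref, r.alt) for r in selection.records]
        expected = brute_force_target_specific(path, ["mutA", "mutB"], ["wt1", "wt2"])
        assert got == expected
        assert ("chr1", 100, "A", "G") in got and ("chr1", 500, "A", "T") in got

    def test_selection_invariant_to_accession_order(self, six_site_vcf):
        path, _ = six_site_vcf
        matrix = load_matrix(path, REF_LENGTH)
        a = target_specific(matrix, ["mutA", "mutB"], ["wt1", "wt2"])
        b = target_specific(matrix, ["mutB", "mutA"], ["wt2", "wt1"])
        assert np.array_equal(a.indices, b.indices)

    def test_swapped_partitions_are_disjoint(self, six_site_vcf):
        path, _ = six_site_vcf
        matrix = load_matrix(path, REF_LENGTH)
        fwd = set(target_specific(matrix, ["mutA", "mutB"], ["wt1", "wt2"]).indices.tolist())
        rev = set(target_specific(matrix, ["wt1", "wt2"], ["mutA", "mutB"]).indices.tolist())
        assert not (fwd & rev)

    def test_invalid_partitions_rejected(self, six_site_vcf):
        path, _ = six_site_vcf
        matrix = load_matrix(path, REF_LENGTH)
        with pytest.raises(ValueError, match="overlap"):
            target_specific(matrix, ["mutA"], ["mutA", "wt1"])
        with pytest.raises(ValueError, match="unknown accession"):
            target_specific(matrix, ["nope"], ["wt1"])
        with pytest.raises(ValueError, match="non-empty"):
            target_specific(matrix, [], ["wt1"])

    def test_random_matrix_matches_brute_force_scan(self, tmp_path):
        # 600 sites x 6 accessions of random genotypes, incl. multi-allelics
        rng = np.random.default_rng(404)
        samples = [f"s{i}" for i in range(6)]
        gt_pool = ["0/0", "0/1", "1/1", "./."]
        gt_pool_ma = ["0/0", "0/1", "1/1", "0/2", "1/2", "2/2", "./."]
        rows = []
        pos = 0
        for _ in range(600):
            pos += int(rng.integers(1, 100))
            if rng.random() < 0.15:
                alts, pool = ["C", "T"], gt_pool_ma
            else:
                alts, pool = ["T"], gt_pool
            gts = [pool[i] for i in rng.integers(len(pool), size=6)]
            rows.append(("chr1", pos, "A", alts, gts, None))
        path = write_panel_vcf(tmp_path / "rand.vcf", samples, rows)
        matrix = load_matrix(path, REF_LENGTH)
        targets, comparators = ["s0", "s1"], ["s2", "s3", "s4"]
        got = [(r.chrom, r.pos, r.ref, r.alt)
               for r in target_specific(matrix, targets, comparators).records]
        assert got == brute_force_target_specific(path, targets, comparators)


class TestDifferenceRate:
    def test_self_comparison_is_zero(self, six_site_vcf):
        path, _ = six_site_vcf
        matrix = load_matrix(path, REF_LENGTH)
        assert pairwise_difference_rate(matrix, "mutA", "mutA") == 0.0

    def test_direct_ratio(self, tmp_path):
        rows = [
            ("chr1", 10, "A", ["T"], ["1/1", "0/0"], None),
            ("chr1", 20, "C", ["G"], ["1/1", "0/0"], None),
            ("chr1", 30, "G", ["A"], ["1/1", "1/1"], None),
        ]
        path = write_panel_vcf(tmp_path / "two.vcf", ["a", "b"], rows)
        matrix = load_matrix(path, REF_LENGTH)
        assert pairwise_difference_rate(matrix, "a", "b") == pytest.approx(2e-6)

    def test_symmetry_and_het_handling(self, six_site_vcf):
        path, _ = six_site_vcf
        matrix = load_matrix(path, REF_LENGTH)
        for a in matrix.samples:
            for b in matrix.samples:
                assert pairwise_difference_rate(matrix, a, b) == pairwise_difference_rate(
                    matrix, b, a
                )
        # het vs hom counts by default but not under hom_only
        default = pairwise_difference_rate(matrix, "mutA", "mutB")
        restricted = pairwise_difference_rate(matrix, "mutA", "mutB", hom_only=True)
        assert default == pytest.approx(1e-6)  # only the het site 200 differs
        assert restricted == 0.0

    def test_triangle_inequality_on_panel(self, demo_dataset):
        matrix = load_matrix(
            demo_dataset["paths"]["vcf"], demo_dataset["manifest"]["reference"]["length"]
        )
        names = matrix.samples
        rate = {
            (a, b): pairwise_difference_rate(matrix, a, b) for a in names for b in names
        }
        for a in names:
            for b in names:
                for c in names:
                    assert rate[a, b] <= rate[a, c] + rate[c, b] + 1e-15

    def test_rate_matches_truth_manifest_replay(self, demo_dataset):
        """Replaying genotypes from truth.json alone reproduces every rate."""
        manifest = demo_dataset["manifest"]
        matrix = load_matrix(demo_dataset["paths"]["vcf"], manifest["reference"]["length"])

        calls = {}  # pos -> {accession: 0|1|2|None}
        def set_hom(pos, carriers):
            calls.setdefault(pos, {})
            for name in carriers:
                calls[pos][name] = 2
        for name, info in manifest["accessions"].items():
            for v in info["private"]:
                set_hom(v["pos"], [name])
        for clade in manifest["clades"]:
            for v in clade["variants"]:
                set_hom(v["pos"], clade["members"])
        if manifest["planted"]:
            set_hom(manifest["planted"]["pos"], manifest["planted"]["carriers"])
        for event in manifest["noise"]:
            calls[event["pos"]][event["accession"]] = (
                1 if event["genotype"] == "0/1" else None
            )

        length = manifest["reference"]["length"]
        for a in manifest["samples"]:
            for b in manifest["samples"]:
                expected = 0
                for pos, site in calls.items():
                    ga, gb = site.get(a, 0), site.get(b, 0)
                    if ga is None or gb is None:
                        continue
                    if ga != gb:
                        expected += 1
                assert pairwise_difference_rate(matrix, a, b) == pytest.approx(
                    expected / length
                ), (a, b)

    def test_similarity_table_is_complement(self, six_site_vcf):
        path, _ = six_site_vcf
        matrix = load_matrix(path, REF_LENGTH)
        table = similarity_table(matrix)
        assert np.allclose(table["similarity"], 1.0 - table["difference_rate"])
        assert len(table) == 6  # 4 choose 2
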