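import numpy as np
import pytest

from pgxpop.tables import AlleleDefinitionTable, State, TranslationTable, VariantKey


@pytest.fixture(scope="session")
def panel():
    from pgxpop.datasets import load_panel

    return load_panel()


@pytest.fixture
def toy_table():
    """Two-variant table: *1 all-REF, *2 = (ALT, REF), *3 = (ALT, ALT)."""
    variants = [
        VariantKey("1", 100, "A", "G", "rs100"),
        VariantKey("1", 200, "C", "T", "rs200"),
    ]
    return AlleleDefinitionTable(
        gene="TOY",
        reference_allele_name="*1",
        variants=variants,
        definitions={
            "*1": np.array([State.REF, State.REF], dtype=np.int8),
            "*2": np.array([State.ALT, State.REF], dtype=np.int8),
            "*3": np.array([State.ALT, State.ALT], dtype=np.int8),
        },
        suballele_map={"*2.001": "*2"},
    )


@pytest.fixture
def toy_translation():
    entries = {}
    for a, b, ph, actionable in [
        ("*1", "*1", "Normal metabolizer", False),
        ("*1", "*2", "Intermediate metabolizer", True),
        ("*2", "*2", "Poor metabolizer", True),
        ("*1", "*3", "Intermediate metabolizer", True),
        ("*2", "*3", "Poor metabolizer", True),
        ("*3", "*3", "Poor metabolizer", True),
    ]:
        pr = "Abnormal/Priority/High Risk" if actionable else "Normal/Routine/Low Risk"
        entries[(a, b)] = (ph, pr)
    return TranslationTable("TOY", entries)


def write_vcf(path, samples, records):
    """Hand-written minimal VCFv4.2 text, independent of the package writer.

    ``records`` is a list of (chrom, pos, rsid, ref, alt, [gt strings]).
    """
    lines = ["##fileformat=VCFv4.2"]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(r[0] for r in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, rsid, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{rsid or '.'}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)
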