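import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from residuelink import fixtures, pipeline


def make_jats(paragraphs, licence="open", pdb_ids=(), doi="10.1107/test.0001"):
    """Assemble a minimal JATS article from paragraph strings."""
    from lxml import etree

    nsmap = {"xlink": "http://www.w3.org/1999/xlink"}
    article = etree.Element("article", nsmap=nsmap)
    front = etree.SubElement(article, "front")
    meta = etree.SubElement(front, "article-meta")
    el = etree.SubElement(meta, "article-id", attrib={"pub-id-type": "doi"})
    el.text = doi
    if licence is not None:
        permissions = etree.SubElement(meta, "permissions")
        ltype = "open-access" if licence == "open" else "proprietary"
        etree.SubElement(permissions, "license", attrib={"license-type": ltype})
    body = etree.SubElement(article, "body")
    sec = etree.SubElement(body, "sec")
    title = etree.SubElement(sec, "title")
    title.text = "Results"
    for text in paragraphs:
        p = etree.SubElement(sec, "p")
        p.text = text
    for pdb_id in pdb_ids:
        p = etree.SubElement(sec, "p")
        p.text = "Coordinates were deposited as entry "
        link = etree.SubElement(
            p,
            "ext-link",
            attrib={
                "ext-link-type": "pdb",
                "{http://www.w3.org/1999/xlink}href": f"https://example.org/{pdb_id}",
            },
        )
        link.text = pdb_id
        link.tail = "."
    return etree.tostring(article, xml_declaration=True, encoding="UTF-8")


@pytest.fixture(scope="session")
def default_bundle():
    return fixtures.generate(fixtures.FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    b = default_bundle
    return pipeline.annotate_article(b.jats_xml, b.sifts_xml, b.validation_xml, b.lookup)
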