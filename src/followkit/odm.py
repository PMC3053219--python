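"""Reader/writer for the ODM-style XML dialect of the follow-up form.

The supported dialect is a documented subset of CDISC ODM 1.3.1: one
``Study`` whose ``MetaDataVersion`` defines the generic follow-up form as
five item groups (identity, diagnosis, therapy, study data, follow-up
data) plus per-department code lists for status and study vocabularies,
and one ``ClinicalData`` block with one ``FormData`` per documentation
event.  Status code-list items carry the OS/EFS event flags as ``Alias``
elements (contexts ``OS`` and ``EFS``); item definitions may carry opaque
concept annotation codes (e.g. SNOMED CT) as ``Alias`` elements with
context ``concept`` — these are round-tripped but never interpreted.

Dates are serialized as ISO 8601 truncated forms (``YYYY``, ``YYYY-MM``,
``YYYY-MM-DD``); the precision of an imprecise date is inferred from the
string length.  Serialization is deterministic: identical documents yield
byte-identical XML.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import IO

from .dates import ImpreciseDate
from .model import (
    DEFAULT_MAPPINGS,
    FollowUpForm,
    FormDocument,
    StatusMapping,
    ValidationError,
)

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"

STUDY_OID = "ST.followup"
MDV_OID = "MDV.1"
FORM_OID = "F.followup"

#: The five item groups of the generic form and the items each contains.
#: patient_pseudonym lives on SubjectData/@SubjectKey, form_id on
#: FormData/@FormRepeatKey; they are not ItemData.
ITEM_GROUPS: dict[str, tuple[str, ...]] = {
    "identity": ("department",),
    "diagnosis": ("diagnosis_date", "diagnosis_text", "diagnosis_classification"),
    "therapy": ("therapy_date", "therapy_text", "therapy_classification"),
    "study_data": ("study",),
    "followup_data": (
        "followup_date",
        "status_label",
        "source",
        "entry_mode",
        "entry_timestamp",
    ),
}

_ITEM_TYPES = {
    "diagnosis_date": "partialDate",
    "therapy_date": "partialDate",
    "followup_date": "partialDate",
    "entry_timestamp": "integer",
}

_DATE_ITEMS = {"diagnosis_date", "therapy_date", "followup_date"}


class OdmParseError(ValueError):
    """Malformed XML or a document outside the supported dialect."""


def _q(tag: str) -> str:
    return f"{{{ODM_NS}}}{tag}"


# ---------------------------------------------------------------------------
# Writing


def _item_value(form: FollowUpForm, item: str) -> str | None:
    value = getattr(form, item)
    if value is None:
        return None
    if isinstance(value, ImpreciseDate):
        return value.isoformat()
    return str(value)


def write_odm(doc: FormDocument) -> str:
    """Serialize a :class:`FormDocument` to the ODM dialect.

    Validates document invariants first (nothing is written for an invalid
    document) and produces deterministic output: stable element ordering
    and no embedded timestamps unless present in ``doc.metadata``.
    """
    doc.validate()

    root = ET.Element(
        "ODM",
        {
            "xmlns": ODM_NS,
            "FileOID": doc.metadata.get("file_oid", "followkit.followup"),
            "FileType": "Snapshot",
            "ODMVersion": "1.3.1",
        },
    )
    if "creation_datetime" in doc.metadata:
        root.set("CreationDateTime", doc.metadata["creation_datetime"])

    study = ET.SubElement(root, "Study", {"OID": STUDY_OID})
    gv = ET.SubElement(study, "GlobalVariables")
    ET.SubElement(gv, "StudyName").text = doc.metadata.get(
        "study_name", "Follow-up documentation"
    )
    ET.SubElement(gv, "StudyDescription").text = doc.metadata.get(
        "study_description", "Generic oncological follow-up form"
    )
    ET.SubElement(gv, "ProtocolName").text = doc.metadata.get(
        "protocol_name", "follow-up"
    )

    mdv = ET.SubElement(
        study, "MetaDataVersion", {"OID": MDV_OID, "Name": "Follow-up form"}
    )
    form_def = ET.SubElement(
        mdv, "FormDef", {"OID": FORM_OID, "Name": "Follow-up", "Repeating": "Yes"}
    )
    for group in ITEM_GROUPS:
        ET.SubElement(
            form_def,
            "ItemGroupRef",
            {"ItemGroupOID": f"IG.{group}", "Mandatory": "No"},
        )
    for group, items in ITEM_GROUPS.items():
        ig = ET.SubElement(
            mdv,
            "ItemGroupDef",
            {"OID": f"IG.{group}", "Name": group, "Repeating": "No"},
        )
        for item in items:
            ET.SubElement(
                ig, "ItemRef", {"ItemOID": f"IT.{item}", "Mandatory": "No"}
            )
    for group, items in ITEM_GROUPS.items():
        for item in items:
            item_def = ET.SubElement(
                mdv,
                "ItemDef",
                {
                    "OID": f"IT.{item}",
                    "Name": item,
                    "DataType": _ITEM_TYPES.get(item, "text"),
                },
            )
            code = doc.item_annotations.get(item)
            if code is not None:
                ET.SubElement(
                    item_def, "Alias", {"Context": "concept", "Name": code}
                )

    for department in sorted(doc.code_lists):
        mapping = doc.code_lists[department]
        cl = ET.SubElement(
            mdv,
            "CodeList",
            {
                "OID": f"CL.status.{department}",
                "Name": f"status.{department}",
                "DataType": "text",
            },
        )
        for label, os_flag, efs_flag in mapping.entries:
            cli = ET.SubElement(cl, "CodeListItem", {"CodedValue": label})
            decode = ET.SubElement(cli, "Decode")
            ET.SubElement(decode, "TranslatedText").text = label
            ET.SubElement(cli, "Alias", {"Context": "OS", "Name": str(os_flag)})
            ET.SubElement(cli, "Alias", {"Context": "EFS", "Name": str(efs_flag)})
    for department in sorted(doc.study_lists):
        cl = ET.SubElement(
            mdv,
            "CodeList",
            {
                "OID": f"CL.study.{department}",
                "Name": f"study.{department}",
                "DataType": "text",
            },
        )
        for label in doc.study_lists[department]:
            cli = ET.SubElement(cl, "CodeListItem", {"CodedValue": label})
            decode = ET.SubElement(cli, "Decode")
            ET.SubElement(decode, "TranslatedText").text = label

    clinical = ET.SubElement(
        root,
        "ClinicalData",
        {"StudyOID": STUDY_OID, "MetaDataVersionOID": MDV_OID},
    )
    # Forms grouped by patient in order of first appearance; within a
    # patient, document order is preserved.
    for patient, forms in _grouped_in_order(doc.forms):
        subject = ET.SubElement(clinical, "SubjectData", {"SubjectKey": patient})
        for form in forms:
            form_data = ET.SubElement(
                subject,
                "FormData",
                {"FormOID": FORM_OID, "FormRepeatKey": form.form_id},
            )
            for group, items in ITEM_GROUPS.items():
                values = [(item, _item_value(form, item)) for item in items]
                values = [(i, v) for i, v in values if v is not None]
                if not values:
                    continue
                ig = ET.SubElement(
                    form_data, "ItemGroupData", {"ItemGroupOID": f"IG.{group}"}
                )
                for item, value in values:
                    ET.SubElement(
                        ig, "ItemData", {"ItemOID": f"IT.{item}", "Value": value}
                    )

    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def _grouped_in_order(
    forms: list[FollowUpForm],
) -> list[tuple[str, list[FollowUpForm]]]:
    order: list[str] = []
    grouped: dict[str, list[FollowUpForm]] = {}
    for form in forms:
        if form.patient_pseudonym not in grouped:
            order.append(form.patient_pseudonym)
            grouped[form.patient_pseudonym] = []
        grouped[form.patient_pseudonym].append(form)
    return [(p, grouped[p]) for p in order]


# ---------------------------------------------------------------------------
# Parsing


def parse_odm(document: str | bytes) -> FormDocument:
    """Parse an ODM-dialect document into a :class:`FormDocument`.

    One :class:`FollowUpForm` is produced per ``FormData`` element; missing
    optional items yield absent (``None``) fields, never dropped forms.
    Code lists and annotation codes are attached as document metadata.

    Raises :class:`OdmParseError` naming the line for malformed XML and
    :class:`~followkit.model.VocabularyError` when a form's status label
    does not resolve against its department's code list.
    """
    if isinstance(document, bytes):
        document = document.decode("utf-8")
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line, col = exc.position
        raise OdmParseError(
            f"malformed XML at line {line}, column {col}: {exc.msg}"
        ) from None
    if root.tag != _q("ODM"):
        raise OdmParseError(
            f"root element is {root.tag!r}, expected ODM in namespace {ODM_NS}"
        )

    doc = FormDocument()
    if root.get("FileOID"):
        doc.metadata["file_oid"] = root.get("FileOID")
    if root.get("CreationDateTime"):
        doc.metadata["creation_datetime"] = root.get("CreationDateTime")

    study = root.find(_q("Study"))
    if study is None:
        raise OdmParseError("document has no Study element")
    gv = study.find(_q("GlobalVariables"))
    if gv is not None:
        for tag, key in (
            ("StudyName", "study_name"),
            ("StudyDescription", "study_description"),
            ("ProtocolName", "protocol_name"),
        ):
            el = gv.find(_q(tag))
            if el is not None and el.text:
                doc.metadata[key] = el.text

    mdv = study.find(_q("MetaDataVersion"))
    if mdv is None:
        raise OdmParseError("Study has no MetaDataVersion element")

    for item_def in mdv.findall(_q("ItemDef")):
        name = item_def.get("Name", "")
        for alias in item_def.findall(_q("Alias")):
            if alias.get("Context") == "concept":
                doc.item_annotations[name] = alias.get("Name", "")

    for code_list in mdv.findall(_q("CodeList")):
        name = code_list.get("Name", "")
        kind, _, department = name.partition(".")
        if kind == "status" and department:
            entries = []
            for cli in code_list.findall(_q("CodeListItem")):
                label = cli.get("CodedValue", "")
                flags = {"OS": 0, "EFS": 0}
                for alias in cli.findall(_q("Alias")):
                    ctx = alias.get("Context")
                    if ctx in flags:
                        flags[ctx] = int(alias.get("Name", "0"))
                entries.append((label, flags["OS"], flags["EFS"]))
            doc.code_lists[department] = StatusMapping(
                department=department, entries=tuple(entries)
            )
        elif kind == "study" and department:
            doc.study_lists[department] = tuple(
                cli.get("CodedValue", "")
                for cli in code_list.findall(_q("CodeListItem"))
            )

    clinical = root.find(_q("ClinicalData"))
    if clinical is not None:
        doc_order = 0
        for subject in clinical.findall(_q("SubjectData")):
            patient = subject.get("SubjectKey")
            if not patient:
                raise OdmParseError("SubjectData without SubjectKey")
            for form_data in subject.findall(_q("FormData")):
                form_id = form_data.get("FormRepeatKey")
                if not form_id:
                    raise OdmParseError(
                        f"FormData of subject {patient!r} lacks FormRepeatKey"
                    )
                fields: dict[str, object] = {}
                for ig in form_data.findall(_q("ItemGroupData")):
                    for item_data in ig.findall(_q("ItemData")):
                        oid = item_data.get("ItemOID", "")
                        item = oid.removeprefix("IT.")
                        value = item_data.get("Value", "")
                        if item in _DATE_ITEMS:
                            fields[item] = ImpreciseDate.parse(value)
                        elif item == "entry_timestamp":
                            fields[item] = int(value)
                        else:
                            fields[item] = value
                if "department" not in fields:
                    raise OdmParseError(
                        f"form {form_id!r} of subject {patient!r} lacks a "
                        f"department item"
                    )
                # Dedup needs a total order; fall back to document order
                # when the input carries no entry timestamp.
                if "entry_timestamp" not in fields:
                    fields["entry_timestamp"] = doc_order
                doc.forms.append(
                    FollowUpForm(
                        patient_pseudonym=patient, form_id=form_id, **fields
                    )
                )
                doc_order += 1

    if not doc.code_lists:
        doc.code_lists = dict(DEFAULT_MAPPINGS)
    doc.validate()
    return doc


def read_odm(path_or_file: str | IO[str]) -> FormDocument:
    """Read an ODM document from a path or open text file."""
    if hasattr(path_or_file, "read"):
        return parse_odm(path_or_file.read())
    with open(path_or_file, "r", encoding="utf-8") as fh:
        return parse_odm(fh.read())


def write_odm_file(doc: FormDocument, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_odm(doc))
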