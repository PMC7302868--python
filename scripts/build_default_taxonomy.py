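"""Regenerate the packaged default condition taxonomy.

Writes src/clockshift/data/default_taxonomy.csv: an exhaustive, non-overlapping
partition of the ICD-10 three-character prefix space (A00..Z99) into 263
condition classes nested under 31 biological systems, following the WHO ICD-10
chapter/block structure.  Each class is defined by its starting prefix; the
closed end of its interval is the predecessor of the next starting prefix, so
exhaustiveness and non-overlap hold by construction.
"""
from __future__ import annotations

import csv
import pathlib

# (system_id, system_name, ambiguous, [(start_prefix, class_name), ...])
SYSTEMS = [
    ("infectious_a", "Infectious diseases: bacterial and other", False, [
        ("A00", "Intestinal infectious diseases"),
        ("A15", "Tuberculosis"),
        ("A20", "Certain zoonotic bacterial diseases"),
        ("A30", "Other bacterial diseases"),
        ("A50", "Infections with a predominantly sexual mode of transmission"),
        ("A65", "Other spirochaetal diseases"),
        ("A70", "Other diseases caused by chlamydiae"),
        ("A75", "Rickettsioses"),
        ("A80", "Viral infections of the central nervous system"),
        ("A92", "Arthropod-borne viral fevers and viral haemorrhagic fevers"),
    ]),
    ("infectious_b", "Infectious diseases: viral, mycotic and parasitic", False, [
        ("B00", "Viral infections characterized by skin and mucous membrane lesions"),
        ("B15", "Viral hepatitis"),
        ("B20", "Human immunodeficiency virus disease"),
        ("B25", "Other viral diseases"),
        ("B35", "Mycoses"),
        ("B50", "Protozoal diseases"),
        ("B65", "Helminthiases"),
        ("B85", "Pediculosis, acariasis and other infestations"),
        ("B90", "Sequelae of infectious and parasitic diseases"),
        ("B95", "Bacterial, viral and other infectious agents"),
        ("B99", "Other infectious diseases"),
    ]),
    ("neoplasms_malignant", "Malignant neoplasms", False, [
        ("C00", "Malignant neoplasms of lip, oral cavity and pharynx"),
        ("C15", "Malignant neoplasms of digestive organs"),
        ("C30", "Malignant neoplasms of respiratory and intrathoracic organs"),
        ("C40", "Malignant neoplasms of bone and articular cartilage"),
        ("C43", "Melanoma and other malignant neoplasms of skin"),
        ("C45", "Malignant neoplasms of mesothelial and soft tissue"),
        ("C50", "Malignant neoplasm of breast"),
        ("C51", "Malignant neoplasms of female genital organs"),
        ("C60", "Malignant neoplasms of male genital organs"),
        ("C64", "Malignant neoplasms of urinary tract"),
        ("C69", "Malignant neoplasms of eye, brain and central nervous system"),
        ("C73", "Malignant neoplasms of thyroid and other endocrine glands"),
        ("C76", "Malignant neoplasms of ill-defined, secondary and unspecified sites"),
        ("C81", "Hodgkin and non-Hodgkin lymphomas"),
        ("C86", "Other lymphoid, haematopoietic and related malignancies"),
        ("C97", "Malignant neoplasms of independent multiple sites"),
    ]),
    ("neoplasms_other", "In situ, benign and uncertain neoplasms", False, [
        ("D00", "In situ neoplasms"),
        ("D10", "Benign neoplasms"),
        ("D37", "Neoplasms of uncertain or unknown behaviour"),
    ]),
    ("blood_immune", "Blood, blood-forming organs and immune mechanism", False, [
        ("D50", "Nutritional anaemias"),
        ("D55", "Haemolytic anaemias"),
        ("D60", "Aplastic and other anaemias"),
        ("D65", "Coagulation defects, purpura and other haemorrhagic conditions"),
        ("D70", "Other diseases of blood and blood-forming organs"),
        ("D80", "Certain disorders involving the immune mechanism"),
    ]),
    ("endocrine", "Endocrine glands", False, [
        ("E00", "Disorders of thyroid gland"),
        ("E10", "Diabetes mellitus"),
        ("E15", "Other disorders of glucose regulation and pancreatic secretion"),
        ("E20", "Disorders of other endocrine glands"),
    ]),
    ("metabolic", "Nutritional and metabolic diseases", False, [
        ("E40", "Malnutrition"),
        ("E50", "Other nutritional deficiencies"),
        ("E65", "Obesity and other hyperalimentation"),
        ("E70", "Metabolic disorders"),
    ]),
    ("mental", "Mental and behavioural disorders", False, [
        ("F00", "Organic, including symptomatic, mental disorders"),
        ("F10", "Mental and behavioural disorders due to psychoactive substance use"),
        ("F20", "Schizophrenia, schizotypal and delusional disorders"),
        ("F30", "Mood [affective] disorders"),
        ("F40", "Neurotic, stress-related and somatoform disorders"),
        ("F50", "Behavioural syndromes associated with physiological disturbances"),
        ("F60", "Disorders of adult personality and behaviour"),
        ("F70", "Mental retardation"),
        ("F80", "Disorders of psychological development"),
        ("F90", "Behavioural and emotional disorders with onset in childhood"),
        ("F99", "Unspecified mental disorder"),
    ]),
    ("nervous", "Nervous system", False, [
        ("G00", "Inflammatory diseases of the central nervous system"),
        ("G10", "Systemic atrophies primarily affecting the central nervous system"),
        ("G20", "Extrapyramidal and movement disorders"),
        ("G30", "Other degenerative diseases of the nervous system"),
        ("G35", "Demyelinating diseases of the central nervous system"),
        ("G40", "Episodic and paroxysmal disorders"),
        ("G50", "Nerve, nerve root and plexus disorders"),
        ("G60", "Polyneuropathies and other disorders of the peripheral nervous system"),
        ("G70", "Diseases of myoneural junction and muscle"),
        ("G80", "Cerebral palsy and other paralytic syndromes"),
        ("G90", "Other disorders of the nervous system"),
    ]),
    ("eye", "Eye and adnexa", False, [
        ("H00", "Disorders of eyelid, lacrimal system and orbit"),
        ("H10", "Disorders of conjunctiva"),
        ("H15", "Disorders of sclera, cornea, iris and ciliary body"),
        ("H25", "Disorders of lens"),
        ("H30", "Disorders of choroid and retina"),
        ("H40", "Glaucoma"),
        ("H43", "Disorders of vitreous body and globe"),
        ("H46", "Disorders of optic nerve and visual pathways"),
        ("H49", "Disorders of ocular muscles, binocular movement and refraction"),
        ("H53", "Visual disturbances and blindness"),
        ("H55", "Other disorders of eye and adnexa"),
    ]),
    ("ear", "Ear and mastoid process", False, [
        ("H60", "Diseases of external ear"),
        ("H65", "Diseases of middle ear and mastoid"),
        ("H80", "Diseases of inner ear"),
        ("H90", "Hearing loss and other disorders of ear"),
    ]),
    ("circulatory", "Circulatory system", False, [
        ("I00", "Acute rheumatic fever"),
        ("I05", "Chronic rheumatic heart diseases"),
        ("I10", "Hypertensive diseases"),
        ("I20", "Ischaemic heart diseases"),
        ("I26", "Pulmonary heart disease and diseases of pulmonary circulation"),
        ("I30", "Other forms of heart disease"),
        ("I60", "Cerebrovascular diseases"),
        ("I70", "Diseases of arteries, arterioles and capillaries"),
        ("I80", "Diseases of veins, lymphatic vessels and lymph nodes"),
        ("I95", "Other and unspecified disorders of the circulatory system"),
    ]),
    ("respiratory", "Respiratory system", False, [
        ("J00", "Acute upper respiratory infections"),
        ("J09", "Influenza and pneumonia"),
        ("J20", "Other acute lower respiratory infections"),
        ("J30", "Other diseases of upper respiratory tract"),
        ("J40", "Chronic lower respiratory diseases"),
        ("J60", "Lung diseases due to external agents"),
        ("J80", "Other respiratory diseases principally affecting the interstitium"),
        ("J85", "Suppurative and necrotic conditions of lower respiratory tract"),
        ("J90", "Other diseases of pleura"),
        ("J95", "Other diseases of the respiratory system"),
    ]),
    ("oral", "Oral cavity, salivary glands and jaws", False, [
        ("K00", "Disorders of tooth development, eruption and hard tissues"),
        ("K09", "Other disorders of oral cavity, salivary glands and jaws"),
    ]),
    ("digestive", "Digestive system", False, [
        ("K20", "Diseases of oesophagus, stomach and duodenum"),
        ("K35", "Diseases of appendix"),
        ("K40", "Hernia"),
        ("K50", "Noninfective enteritis and colitis"),
        ("K55", "Other diseases of intestines"),
        ("K65", "Diseases of peritoneum"),
        ("K70", "Diseases of liver"),
        ("K80", "Disorders of gallbladder, biliary tract and pancreas"),
        ("K90", "Other diseases of the digestive system"),
    ]),
    ("skin", "Skin and subcutaneous tissue", False, [
        ("L00", "Infections of the skin and subcutaneous tissue"),
        ("L10", "Bullous disorders"),
        ("L20", "Dermatitis and eczema"),
        ("L40", "Papulosquamous disorders"),
        ("L50", "Urticaria and erythema"),
        ("L55", "Radiation-related disorders of the skin"),
        ("L60", "Disorders of skin appendages"),
        ("L80", "Other disorders of the skin and subcutaneous tissue"),
    ]),
    ("musculoskeletal", "Musculoskeletal system and connective tissue", False, [
        ("M00", "Infectious arthropathies"),
        ("M05", "Inflammatory polyarthropathies"),
        ("M15", "Arthrosis"),
        ("M20", "Other joint disorders"),
        ("M30", "Systemic connective tissue disorders"),
        ("M40", "Deforming dorsopathies"),
        ("M45", "Spondylopathies"),
        ("M50", "Other dorsopathies"),
        ("M60", "Disorders of muscles"),
        ("M65", "Disorders of synovium and tendon"),
        ("M70", "Other soft tissue disorders"),
        ("M80", "Disorders of bone density and structure"),
        ("M86", "Other osteopathies"),
        ("M91", "Chondropathies"),
        ("M95", "Other disorders of the musculoskeletal system and connective tissue"),
    ]),
    ("genitourinary", "Genitourinary system", False, [
        ("N00", "Glomerular diseases"),
        ("N10", "Renal tubulo-interstitial diseases"),
        ("N17", "Renal failure"),
        ("N20", "Urolithiasis"),
        ("N25", "Other disorders of kidney and ureter"),
        ("N30", "Other diseases of urinary system"),
        ("N40", "Diseases of male genital organs"),
        ("N60", "Disorders of breast"),
        ("N70", "Inflammatory diseases of female pelvic organs"),
        ("N80", "Noninflammatory disorders of female genital tract"),
        ("N99", "Other disorders of the genitourinary system"),
    ]),
    ("pregnancy", "Pregnancy, childbirth and the puerperium", False, [
        ("O00", "Pregnancy with abortive outcome"),
        ("O10", "Oedema, proteinuria and hypertensive disorders in pregnancy"),
        ("O20", "Other maternal disorders predominantly related to pregnancy"),
        ("O30", "Maternal care related to the fetus and amniotic cavity"),
        ("O60", "Complications of labour and delivery"),
        ("O80", "Delivery"),
        ("O85", "Complications predominantly related to the puerperium"),
        ("O94", "Other obstetric conditions"),
    ]),
    ("perinatal", "Conditions originating in the perinatal period", False, [
        ("P00", "Fetus and newborn affected by maternal factors and complications"),
        ("P05", "Disorders related to length of gestation and fetal growth"),
        ("P10", "Birth trauma"),
        ("P20", "Respiratory and cardiovascular disorders of the perinatal period"),
        ("P35", "Infections specific to the perinatal period"),
        ("P50", "Haemorrhagic and haematological disorders of fetus and newborn"),
        ("P70", "Transitory endocrine and metabolic disorders of fetus and newborn"),
        ("P75", "Digestive system disorders of fetus and newborn"),
        ("P80", "Conditions involving the integument and temperature regulation"),
        ("P90", "Other disorders originating in the perinatal period"),
    ]),
    ("congenital", "Congenital malformations and chromosomal abnormalities", False, [
        ("Q00", "Congenital malformations of the nervous system"),
        ("Q10", "Congenital malformations of eye, ear, face and neck"),
        ("Q20", "Congenital malformations of the circulatory system"),
        ("Q30", "Congenital malformations of the respiratory system"),
        ("Q35", "Cleft lip and cleft palate"),
        ("Q38", "Other congenital malformations of the digestive system"),
        ("Q50", "Congenital malformations of genital organs and urinary system"),
        ("Q60", "Congenital malformations of the urinary system"),
        ("Q65", "Congenital malformations and deformations of the musculoskeletal system"),
        ("Q80", "Other congenital malformations"),
        ("Q90", "Chromosomal abnormalities"),
    ]),
    ("symptoms_signs", "Symptoms and signs across various systems", True, [
        ("R00", "Symptoms and signs involving the circulatory and respiratory systems"),
        ("R10", "Symptoms and signs involving the digestive system and abdomen"),
        ("R20", "Symptoms and signs involving the skin and subcutaneous tissue"),
        ("R25", "Symptoms and signs involving the nervous and musculoskeletal systems"),
        ("R30", "Symptoms and signs involving the urinary system"),
        ("R40", "Symptoms and signs involving cognition, perception and behaviour"),
        ("R47", "Symptoms and signs involving speech and voice"),
        ("R50", "General symptoms and signs"),
    ]),
    ("abnormal_findings", "Abnormal clinical and laboratory findings", True, [
        ("R70", "Abnormal findings on examination of blood"),
        ("R80", "Abnormal findings on examination of urine"),
        ("R83", "Abnormal findings on examination of other body fluids and tissues"),
        ("R90", "Abnormal findings on diagnostic imaging and function studies"),
        ("R95", "Ill-defined and unknown causes of mortality"),
    ]),
    ("injuries", "Injuries by body region", False, [
        ("S00", "Injuries to the head"),
        ("S10", "Injuries to the neck"),
        ("S20", "Injuries to the thorax"),
        ("S30", "Injuries to the abdomen, lower back, lumbar spine and pelvis"),
        ("S40", "Injuries to the shoulder and upper arm"),
        ("S50", "Injuries to the elbow and forearm"),
        ("S60", "Injuries to the wrist and hand"),
        ("S70", "Injuries to the hip and thigh"),
        ("S80", "Injuries to the knee and lower leg"),
        ("S90", "Injuries to the ankle and foot"),
    ]),
    ("poisoning", "Poisoning and other consequences of external causes", False, [
        ("T00", "Injuries involving multiple body regions"),
        ("T08", "Injuries to unspecified parts of trunk, limb or body region"),
        ("T15", "Effects of foreign body entering through natural orifice"),
        ("T20", "Burns and corrosions of external body surface"),
        ("T26", "Burns and corrosions of eye and internal organs"),
        ("T29", "Burns and corrosions of multiple and unspecified body regions"),
        ("T33", "Frostbite"),
        ("T36", "Poisoning by drugs, medicaments and biological substances"),
        ("T51", "Toxic effects of substances chiefly nonmedicinal as to source"),
        ("T66", "Other and unspecified effects of external causes"),
        ("T79", "Certain early complications of trauma"),
        ("T80", "Complications of surgical and medical care"),
        ("T90", "Sequelae of injuries, of poisoning and of external causes"),
    ]),
    ("external_transport", "External causes: transport accidents", False, [
        ("V01", "Pedestrian injured in transport accident"),
        ("V10", "Pedal cyclist injured in transport accident"),
        ("V20", "Motorcycle rider injured in transport accident"),
        ("V30", "Occupant of three-wheeled motor vehicle injured in transport accident"),
        ("V40", "Car occupant injured in transport accident"),
        ("V50", "Occupant of pick-up truck or van injured in transport accident"),
        ("V60", "Occupant of heavy transport vehicle injured in transport accident"),
        ("V70", "Bus occupant injured in transport accident"),
        ("V80", "Other land transport accidents"),
        ("V90", "Water, air and other and unspecified transport accidents"),
    ]),
    ("external_accidents", "External causes: other accidents", False, [
        ("W00", "Falls"),
        ("W20", "Exposure to inanimate mechanical forces"),
        ("W50", "Exposure to animate mechanical forces"),
        ("W65", "Accidental drowning and submersion"),
        ("W75", "Other accidental threats to breathing"),
        ("W85", "Exposure to electric current, radiation and extreme temperature"),
        ("X00", "Exposure to smoke, fire and flames"),
        ("X10", "Contact with heat and hot substances"),
        ("X20", "Contact with venomous animals and plants"),
        ("X30", "Exposure to forces of nature"),
        ("X40", "Accidental poisoning by and exposure to noxious substances"),
        ("X50", "Overexertion, travel and privation"),
        ("X58", "Accidental exposure to other and unspecified factors"),
    ]),
    ("external_intentional", "External causes: intentional", False, [
        ("X60", "Intentional self-harm"),
        ("X85", "Assault"),
    ]),
    ("external_other", "External causes: undetermined, legal and medical", False, [
        ("Y10", "Event of undetermined intent"),
        ("Y35", "Legal intervention and operations of war"),
        ("Y40", "Drugs, medicaments and biological substances causing adverse effects"),
        ("Y60", "Misadventures to patients during surgical and medical care"),
        ("Y70", "Medical devices associated with adverse incidents"),
        ("Y83", "Surgical and medical procedures as the cause of abnormal reaction"),
        ("Y85", "Sequelae of external causes of morbidity and mortality"),
        ("Y90", "Supplementary factors related to causes of morbidity and mortality"),
    ]),
    ("health_services", "Factors influencing health status and contact with health services", True, [
        ("Z00", "Persons encountering health services for examination and investigation"),
        ("Z20", "Persons with potential health hazards related to communicable diseases"),
        ("Z30", "Persons encountering health services in circumstances related to reproduction"),
        ("Z40", "Persons encountering health services for specific procedures"),
        ("Z50", "Persons encountering health services for care involving rehabilitation"),
        ("Z55", "Persons with potential health hazards related to socioeconomic circumstances"),
        ("Z70", "Persons encountering health services in other circumstances"),
        ("Z80", "Persons with potential health hazards related to personal and family history"),
    ]),
    ("special", "Codes for special purposes", True, [
        ("U00", "Provisional assignment and special-purpose codes"),
    ]),
]

LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def prefix_index(p: str) -> int:
    return LETTERS.index(p[0]) * 100 + int(p[1:3])


def index_prefix(i: int) -> str:
    return f"{LETTERS[i // 100]}{i % 100:02d}"


def build_rows():
    entries = []
    for sys_id, sys_name, amb, classes in SYSTEMS:
        for start, cname in classes:
            cid = f"{sys_id}:{start}"
            entries.append((prefix_index(start), start, cid, cname, sys_id, sys_name, amb))
    entries.sort()
    starts = [e[0] for e in entries]
    assert starts[0] == prefix_index("A00")
    rows = []
    for i, (idx, start, cid, cname, sys_id, sys_name, amb) in enumerate(entries):
        end = index_prefix(starts[i + 1] - 1) if i + 1 < len(entries) else "Z99"
        rows.append({
            "code_start": start, "code_end": end, "icd_version": 10, "dialect": "*",
            "class_id": cid, "class_name": cname,
            "system_id": sys_id, "system_name": sys_name,
            "ambiguous": int(amb),
        })
    return rows


def main():
    rows = build_rows()
    n_classes = len({r["class_id"] for r in rows})
    n_systems = len({r["system_id"] for r in rows})
    print(f"{n_classes} classes, {n_systems} systems")
    assert n_classes == 263 and n_systems == 31, (n_classes, n_systems)
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "clockshift" / "data" / "default_taxonomy.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with out.open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)
    print(f"wrote {out} ({out.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
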