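<?xml version='1.0' encoding='UTF-8'?>
<algorithm name="anxiety" root="severity">
  <dictionary>
    <variable name="pain_severity" kind="numeric" lower="0" upper="10" resolution="1" units="0-10 self-report" source="patient-reported"/>
    <variable name="anxiety_severity" kind="numeric" lower="0" upper="10" resolution="1" units="0-10 self-report" source="patient-reported"/>
    <variable name="depression_severity" kind="numeric" lower="0" upper="10" resolution="1" units="0-10 self-report" source="patient-reported"/>
    <variable name="dyspnea_severity" kind="numeric" lower="0" upper="10" resolution="1" units="0-10 self-report" source="patient-reported"/>
    <variable name="fatigue_severity" kind="numeric" lower="0" upper="10" resolution="1" units="0-10 self-report" source="patient-reported"/>
    <variable name="bowel_score" kind="numeric" lower="0" upper="4" resolution="1" units="0-4 constipation score" source="patient-reported"/>
    <variable name="pain_quality" kind="categorical" source="patient-reported">
      <category>achy</category>
      <category>sharp</category>
      <category>burning</category>
      <category>shooting</category>
      <category>other</category>
    </variable>
    <variable name="pain_timing" kind="categorical" source="patient-reported">
      <category>intermittent</category>
      <category>constant</category>
    </variable>
    <variable name="age" kind="numeric" lower="21" upper="110" resolution="1" units="years" source="chart"/>
    <variable name="weight" kind="numeric" lower="30" upper="250" resolution="0.1" units="kg" source="chart"/>
    <variable name="sex" kind="categorical" source="chart">
      <category>male</category>
      <category>female</category>
    </variable>
    <variable name="serum_creatinine" kind="numeric" lower="0.2" upper="15.0" resolution="0.1" units="mg/dL" source="chart"/>
    <variable name="platelets" kind="numeric" lower="0" upper="2000000" resolution="1000" units="count/mL" source="chart"/>
    <variable name="gi_bleed_history" kind="boolean" source="chart"/>
    <variable name="alcohol_use" kind="boolean" source="patient-reported"/>
    <variable name="opioid_regimen_adherent" kind="boolean" source="patient-reported"/>
    <variable name="medications" kind="medication-list" source="chart"/>
    <variable name="creatinine_clearance" kind="numeric" lower="0" upper="3000" resolution="0.1" units="mL/min" source="computed" inputs="sex age weight serum_creatinine"/>
    <variable name="opioid_use_class" kind="categorical" source="computed" inputs="medications opioid_regimen_adherent">
      <category>none</category>
      <category>ir-only</category>
      <category>sr-only</category>
      <category>ir-and-sr</category>
      <category>patch-containing</category>
      <category>non-adherent</category>
    </variable>
  </dictionary>
  <terminal id="T-low">
    <recommendation-ref id="toolkit"/>
  </terminal>
  <terminal id="T-mid">
    <recommendation-ref id="medication-review"/>
    <recommendation-ref id="toolkit"/>
  </terminal>
  <terminal id="T-high">
    <recommendation-ref id="supportive-referral"/>
    <recommendation-ref id="toolkit"/>
  </terminal>
  <node id="severity" variable="anxiety_severity">
    <branch target="T-low">
      <predicate variable="anxiety_severity">
        <interval lower="0" upper="3" lower-closed="true" upper-closed="true"/>
      </predicate>
    </branch>
    <branch target="T-mid">
      <predicate variable="anxiety_severity">
        <interval lower="4" upper="6" lower-closed="true" upper-closed="true"/>
      </predicate>
    </branch>
    <branch target="T-high">
      <predicate variable="anxiety_severity">
        <interval lower="7" upper="10" lower-closed="true" upper-closed="true"/>
      </predicate>
    </branch>
  </node>
</algorithm>
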