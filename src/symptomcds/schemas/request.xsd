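<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <!-- The request dialect deliberately has no slots for identifying
       information: patients are referenced by an opaque session token. -->
  <xs:element name="request">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="session" type="xs:string"/>
        <xs:element name="patient">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="value" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="name" use="required">
                        <xs:simpleType>
                          <xs:restriction base="xs:string">
                            <xs:pattern value="[A-Za-z0-9_]+"/>
                          </xs:restriction>
                        </xs:simpleType>
                      </xs:attribute>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
              <xs:element name="medications" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="medication" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="drug" type="xs:string" use="required"/>
                        <xs:attribute name="class" type="xs:string" use="required"/>
                        <xs:attribute name="dose" type="xs:decimal" use="required"/>
                        <xs:attribute name="route" type="xs:string" default="oral"/>
                        <xs:attribute name="schedule" type="xs:string" default=""/>
                        <xs:attribute name="formulation" type="xs:string" default="tablet"/>
                        <xs:attribute name="dose-24h" type="xs:decimal" default="0"/>
                        <xs:attribute name="tablets-per-dose" type="xs:decimal"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="visit-date" type="xs:date"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="algorithms">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="algorithm" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
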